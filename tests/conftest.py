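import numpy as np
import pytest

from coralmet.io import Spectrum
from coralmet.network import _candidate_pairs
from coralmet.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def seed42_dataset():
    """The reference synthetic dataset used by cross-module tests."""
    return generate_dataset(SyntheticConfig(seed=42))


def make_spectrum(fid, precursor, mz, intensities=None, **kw):
    mz = np.asarray(mz, float)
    if intensities is None:
        intensities = np.full(mz.size, 100.0)
    return Spectrum(fid, precursor, np.column_stack([mz, intensities]), **kw)


def brute_force_modified_cosine(a, b, frag_tol=0.02):
    """Exhaustive maximum-weight one-to-one matching over all candidate
    fragment pairs (direct or precursor-shifted); independent oracle for
    the greedy matcher. Returns (score, n_matched at that score)."""
    pairs = _candidate_pairs(a, b, frag_tol, b.precursor_mz - a.precursor_mz)
    best = {"s": 0.0, "n": 0}

    def rec(k, used_a, used_b, acc, cnt):
        if acc > best["s"] + 1e-15 or (
            abs(acc - best["s"]) <= 1e-15 and cnt > best["n"]
        ):
            best["s"], best["n"] = acc, cnt
        if k == len(pairs):
            return
        if acc + sum(p[0] for p in pairs[k:]) < best["s"] - 1e-15:
            return
        s, _e, i, j, _kind = pairs[k]
        if i not in used_a and j not in used_b:
            rec(k + 1, used_a | {i}, used_b | {j}, acc + s, cnt + 1)
        rec(k + 1, used_a, used_b, acc, cnt)

    rec(0, frozenset(), frozenset(), 0.0, 0)
    return best["s"], best["n"]


def random_spectrum_pair(rng):
    """Random <=8-peak spectra with analog-like shared peaks (direct and
    precursor-shifted copies) for the matching oracle suite."""
    def spec(fid, prec, mz, inten):
        return Spectrum(fid, prec, np.column_stack([np.sort(mz), inten]))

    na, nb = rng.integers(2, 9), rng.integers(2, 9)
    prec_a, prec_b = rng.uniform(200, 600, 2)
    a = spec("a", prec_a, rng.uniform(100, 500, na), rng.uniform(1, 100, na))
    mzb = list(rng.uniform(100, 500, nb))
    dp = prec_b - prec_a
    for m in a.mz:
        r = rng.random()
        if r < 0.25:
            mzb.append(m + rng.normal(0, 0.004))
        elif r < 0.5:
            mzb.append(m + dp + rng.normal(0, 0.004))
    mzb = np.asarray(mzb[:8])
    b = spec("b", prec_b, mzb, rng.uniform(1, 100, len(mzb)))
    return a, b


# printed worked-example values: lyso PC P-18:0 and its head-group analogs
LYSO_PC_P180_PARENT = 508.3752
LYSO_PC_P180_FRAGMENTS = (86.0968, 104.1072, 184.0730, 240.0991)
ANALOG_507_PARENT = 507.3549
ANALOG_507_FRAGMENTS = (85.0764, 103.0868, 183.0526, 239.0786)
ANALOG_522_PARENT = 522.3905
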