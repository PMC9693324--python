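"""Synthetic two-group LC-MS/MS dataset generator.

Emulates the structure of an untargeted coral metabolomics study: two
species groups of 8 and 4 colonies, five pooled-QC injections, a spiked
deuterated-caffeine internal standard, log-normal feature abundances with a
planted differential fraction, group-exclusive ("unique") features created
by dropout below a detection floor, and spectral analog families whose
members differ from a seed lipid spectrum by a head-group mass delta and/or
multiples of a CH2 alkyl-chain delta.

Noise model
-----------
Each measured intensity is ``base_i * effect_ig * s_j * eps_ij`` where
``s_j`` is a per-sample injection/extraction scale factor (log-normal,
CV ``sample_scale_cv``) shared by all features of sample ``j``, and
``eps_ij`` is per-feature technical noise (log-normal, CV ``cv_technical``).
The internal standard is spiked at a constant amount, so its measured value
is ``is_level * s_j`` exactly: dividing by it removes the injection scale
and leaves pure technical noise, which is what the QC coefficient of
variation then measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    FeatureTable,
    Spectrum,
    write_mgf,
    write_quant_table,
    write_sample_metadata,
)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "write_dataset"]

# diagnostic head-group fragment series used for seed lipid spectra
# (glycerophosphocholine-type ions)
_HEAD_SERIES = (86.0968, 104.1072, 124.9998, 184.0730, 240.0991)
_SEED_PARENT = 508.3752

INTERNAL_STANDARD_ID = "IS_caffeine_D9"
CAFFEINE_D9_MZ = 204.1469  # [M+H]+ of caffeine-D9


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study design.

    Defaults mirror the emulated study: 8 vs 4 biological samples, five
    pooled-QC injections, 10% differential features at |log2 FC| = 2,
    20% technical CV, and analog families built from head-group deltas of
    1.0204, 11.9997 and 19.9684 Da plus CH2 chain homologs.
    """

    n_group_a: int = 8
    n_group_b: int = 4
    n_qc: int = 5
    n_blank: int = 1
    n_features: int = 500
    frac_differential: float = 0.10
    log2_fold_change: float = 2.0
    cv_technical: float = 0.20
    sample_scale_cv: float = 0.10
    n_analog_families: int = 3
    head_group_deltas: tuple[float, ...] = (1.0204, 11.9997, 19.9684)
    chain_delta: float = 14.0157
    n_chain_homologs: int = 1
    n_unique_a: int = 3
    n_unique_b: int = 10
    sigma_log_range: tuple[float, float] = (0.5, 1.5)
    is_level: float = 1.0e6
    base_intensity: float = 2.0e5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_group_a, self.n_group_b, self.n_features) < 1:
            raise ValueError("group sizes and n_features must be >= 1")
        if self.n_qc < 0:
            raise ValueError("n_qc must be >= 0")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")
        if self.cv_technical <= 0:
            raise ValueError("cv_technical must be > 0")


@dataclass
class GroundTruth:
    """What was planted: differential ids/directions, analog families, IS id."""

    differential_ids: list[str]
    directions: dict[str, str]  # feature id -> "higher_in_A" / "higher_in_B"
    families: list[dict] = field(default_factory=list)
    internal_standard_id: str = INTERNAL_STANDARD_ID
    unique_a_ids: list[str] = field(default_factory=list)
    unique_b_ids: list[str] = field(default_factory=list)

    def family_member_ids(self) -> list[set[str]]:
        return [set(f["member_ids"]) for f in self.families]

    @property
    def all_differential_ids(self) -> set[str]:
        """Every feature with a planted group difference: fold-change
        features plus the group-exclusive (dropout) features, which are
        differential by construction."""
        return set(self.differential_ids) | set(self.unique_a_ids) | set(
            self.unique_b_ids
        )


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size))


def _random_spectrum(
    rng: np.random.Generator, feature_id: str, precursor: float, rt: float
) -> Spectrum:
    n_peaks = int(rng.integers(5, 13))
    mz = np.round(rng.uniform(50.0, max(60.0, precursor - 1.0), n_peaks), 4)
    inten = np.round(rng.uniform(3.0e4, 1.0e6, n_peaks), 1)
    return Spectrum(feature_id, round(precursor, 4), np.column_stack([mz, inten]),
                    retention_time=round(rt, 3))


def _family_spectra(
    rng: np.random.Generator,
    family_index: int,
    head_delta: float,
    chain_delta: float,
    n_chain: int,
    next_id: int,
) -> tuple[list[Spectrum], dict, int]:
    """Build one analog family: a seed lipid, one head-group analog and
    chain homologs. Head fragments move by the head delta; chain fragments
    and the precursor move with the chain delta."""
    rt = rng.uniform(6.0, 12.0)
    # each family emulates a distinct compound class: its own head-group
    # fragment series and parent mass. The two offsets are deliberately
    # unequal so no cross-family precursor delta re-aligns another family's
    # head series (that would be a spurious analog relationship).
    parent = _SEED_PARENT + family_index * 91.37
    chain_frags = np.round(np.sort(rng.uniform(280.0, parent - 20.0, 3)), 4)
    head = np.asarray(_HEAD_SERIES) + family_index * 53.71
    seed_mz = np.concatenate([head, chain_frags])
    seed_int = np.concatenate(
        [
            np.array([2.0e5, 1.5e5, 8.0e4, 9.0e5, 1.2e5]),
            np.round(rng.uniform(1.0e5, 6.0e5, chain_frags.size), 1),
        ]
    )

    def make(fid: str, parent: float, mz: np.ndarray) -> Spectrum:
        jitter = np.round(rng.uniform(0.9, 1.1, seed_int.size), 4)
        peaks = np.column_stack([np.round(mz, 4), np.round(seed_int * jitter, 1)])
        return Spectrum(fid, round(parent, 4), peaks,
                        retention_time=round(rt + rng.uniform(-0.2, 0.2), 3))

    members: list[Spectrum] = []
    truth: dict = {"family_index": family_index, "head_delta": head_delta,
                   "chain_delta": chain_delta, "member_ids": [], "roles": {},
                   "head_series": [round(float(m), 4) for m in head],
                   "seed_parent": round(parent, 4)}

    seed_id = str(next_id)
    next_id += 1
    members.append(make(seed_id, parent, seed_mz))
    truth["member_ids"].append(seed_id)
    truth["roles"][seed_id] = {"role": "seed", "head_shift": 0.0, "chain_units": 0}
    truth["seed_id"] = seed_id

    # head-group analog: head fragments and parent shift by ~head_delta
    # (parent shift differs by 0.0001 Da, as observed shifts do)
    analog_id = str(next_id)
    next_id += 1
    analog_mz = np.concatenate([head - head_delta, chain_frags])
    members.append(make(analog_id, parent - head_delta + 0.0001, analog_mz))
    truth["member_ids"].append(analog_id)
    truth["roles"][analog_id] = {
        "role": "head_analog", "head_shift": -head_delta, "chain_units": 0,
    }

    for k in range(1, n_chain + 1):
        hom_id = str(next_id)
        next_id += 1
        hom_mz = np.concatenate([head, chain_frags + k * chain_delta])
        members.append(make(hom_id, parent + k * chain_delta, hom_mz))
        truth["member_ids"].append(hom_id)
        truth["roles"][hom_id] = {
            "role": "chain_homolog", "head_shift": 0.0, "chain_units": k,
        }
    return members, truth, next_id


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[Spectrum], FeatureTable, GroundTruth]:
    """Generate spectra, quantification table and ground truth.

    The same config (including seed) always produces identical output.
    """
    rng = np.random.default_rng(config.seed)
    c = config

    sample_ids = (
        [f"A{i + 1:02d}" for i in range(c.n_group_a)]
        + [f"B{i + 1:02d}" for i in range(c.n_group_b)]
        + [f"QC{i + 1:02d}" for i in range(c.n_qc)]
        + [f"blank{i + 1:02d}" for i in range(c.n_blank)]
    )
    groups = pd.Series(
        ["A"] * c.n_group_a + ["B"] * c.n_group_b + ["QC"] * c.n_qc
        + ["blank"] * c.n_blank,
        index=sample_ids, name="group",
    )

    # --- spectra ---------------------------------------------------------
    spectra: list[Spectrum] = []
    truth_families: list[dict] = []
    next_id = 1
    for f in range(c.n_analog_families):
        head_delta = c.head_group_deltas[f % len(c.head_group_deltas)]
        members, fam_truth, next_id = _family_spectra(
            rng, f, head_delta, c.chain_delta, c.n_chain_homologs, next_id
        )
        spectra.extend(members)
        truth_families.append(fam_truth)
    n_family_features = next_id - 1
    n_plain = c.n_features - n_family_features - 1  # -1 for the IS
    if n_plain < 0:
        raise ValueError("n_features too small for the requested analog families")
    for _ in range(n_plain):
        fid = str(next_id)
        next_id += 1
        spectra.append(
            _random_spectrum(
                rng, fid, rng.uniform(120.0, 980.0), rng.uniform(0.5, 15.0)
            )
        )
    # internal standard spectrum
    is_peaks = np.column_stack(
        [np.array([138.1026, 204.1469]), np.array([3.0e5, 9.0e5])]
    )
    spectra.append(
        Spectrum(INTERNAL_STANDARD_ID, CAFFEINE_D9_MZ, is_peaks, retention_time=3.2)
    )

    feature_ids = [s.feature_id for s in spectra]
    n_feat = len(feature_ids)

    # --- abundances ------------------------------------------------------
    sigma = rng.uniform(*c.sigma_log_range, n_feat)
    base = c.base_intensity * np.exp(rng.normal(0.0, sigma))

    n_diff = int(round(c.frac_differential * c.n_features))
    if c.frac_differential > 0 and n_diff < 1:
        warnings.warn("frac_differential too small: zero differential features")
    eligible = [fid for fid in feature_ids if fid != INTERNAL_STANDARD_ID]
    diff_ids = list(rng.choice(eligible, size=n_diff, replace=False)) if n_diff else []
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    directions = {
        fid: ("higher_in_A" if s < 0 else "higher_in_B")
        for fid, s in zip(diff_ids, signs)
    }

    remaining = [fid for fid in eligible if fid not in set(diff_ids)]
    unique_a = remaining[: c.n_unique_a]
    unique_b = remaining[c.n_unique_a : c.n_unique_a + c.n_unique_b]
    for fid in unique_a:
        directions[fid] = "higher_in_A"
    for fid in unique_b:
        directions[fid] = "higher_in_B"

    idx = {fid: i for i, fid in enumerate(feature_ids)}
    effect_b = np.ones(n_feat)
    for fid, s in zip(diff_ids, signs):
        effect_b[idx[fid]] = 2.0 ** (s * c.log2_fold_change)

    n_analysis = c.n_group_a + c.n_group_b
    scale = _lognormal_noise(rng, c.sample_scale_cv, len(sample_ids))

    matrix = np.zeros((n_feat, len(sample_ids)))
    mean_a = base
    mean_b = base * effect_b
    pooled = (c.n_group_a * mean_a + c.n_group_b * mean_b) / n_analysis
    for j, sid in enumerate(sample_ids):
        g = groups.iloc[j]
        if g == "A":
            mu = mean_a
        elif g == "B":
            mu = mean_b
        elif g == "QC":
            mu = pooled
        else:  # blank: background only
            mu = np.zeros(n_feat)
        eps = _lognormal_noise(rng, c.cv_technical, n_feat)
        matrix[:, j] = mu * scale[j] * eps

    # internal standard: constant spike, carries only the sample scale
    matrix[idx[INTERNAL_STANDARD_ID], :] = c.is_level * scale

    # dropout: group-exclusive features fall below the detection floor
    col = {sid: j for j, sid in enumerate(sample_ids)}
    b_cols = [col[s] for s in groups.index[groups == "B"]]
    a_cols = [col[s] for s in groups.index[groups == "A"]]
    for fid in unique_a:
        matrix[idx[fid], b_cols] = 0.0
    for fid in unique_b:
        matrix[idx[fid], a_cols] = 0.0

    matrix = np.round(matrix, 3)
    table = FeatureTable(
        intensities=pd.DataFrame(matrix, index=feature_ids, columns=sample_ids),
        feature_mz=pd.Series(
            [s.precursor_mz for s in spectra], index=feature_ids, name="mz"
        ),
        feature_rt=pd.Series(
            [s.retention_time for s in spectra], index=feature_ids, name="rt"
        ),
        sample_group=groups,
    )
    truth = GroundTruth(
        differential_ids=list(diff_ids),
        directions=directions,
        families=truth_families,
        unique_a_ids=unique_a,
        unique_b_ids=unique_b,
    )
    return spectra, table, truth


def write_dataset(
    config: SyntheticConfig, outdir: str | Path
) -> tuple[Path, Path, Path, Path]:
    """Generate and write MGF, quant CSV, sample metadata and ground truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra, table, truth = generate_dataset(config)
    mgf_path = outdir / "spectra.mgf"
    quant_path = outdir / "quant.csv"
    meta_path = outdir / "samples.tsv"
    truth_path = outdir / "ground_truth.tsv"
    write_mgf(spectra, mgf_path)
    write_quant_table(table, quant_path)
    write_sample_metadata(table.sample_group, meta_path)

    rows = []
    for fid in table.feature_ids:
        role = "background"
        family = ""
        if fid == truth.internal_standard_id:
            role = "internal_standard"
        for fam in truth.families:
            if fid in fam["roles"]:
                role = fam["roles"][fid]["role"]
                family = str(fam["family_index"])
        rows.append(
            {
                "feature_id": fid,
                "differential": fid in set(truth.differential_ids),
                "direction": truth.directions.get(fid, ""),
                "family": family,
                "role": role,
                "unique_to": (
                    "A" if fid in truth.unique_a_ids
                    else "B" if fid in truth.unique_b_ids else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
    return mgf_path, quant_path, meta_path, truth_path
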