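"""Library matching, analog annotation by fragment mass shifts, and lipid
unsaturation indices.

Analog annotation formalizes the manual reasoning used to identify unknown
lipids from their network neighbors: if an unknown spectrum shares the
dissociation pattern of an annotated lipid but its diagnostic head-group
fragments are all displaced by one consistent mass delta, the unknown is a
head-group analog; if the head fragments are unchanged and the precursor
moved by a multiple of CH2 (14.01565 Da), it is an alkyl-chain homolog; a
consistent head shift plus a residual parent delta indicates both changes.

All deltas are signed as unknown minus known.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Spectrum
from .network import modified_cosine

__all__ = [
    "LibraryMatch",
    "AnalogHypothesis",
    "LipidSpecies",
    "library_search",
    "propagate_analog",
    "parse_lipid_name",
    "unsaturation_index",
    "abundance_percentages",
    "load_diagnostic_fragments",
]

CH2 = 14.01565  # exact methylene unit, Da


@dataclass
class LibraryMatch:
    feature_id: str
    compound_name: str
    score: float
    n_matched: int
    annotation_level: int = 2  # MSI level 2: spectral library match


@dataclass
class AnalogHypothesis:
    known_id: str
    unknown_id: str
    parent_delta: float  # unknown precursor - known precursor, Da
    fragment_shifts: list[float] = field(default_factory=list)
    consistent_shift: float = float("nan")  # median of fragment_shifts
    shift_dispersion: float = float("nan")  # max |shift - median|
    chain_delta: float = float("nan")  # parent_delta - consistent_shift
    classification: str = "unclassified"
    reason: str = ""


@dataclass
class LipidSpecies:
    name: str
    lipid_class: str
    n_carbons: int
    n_double_bonds: int
    relative_abundance_pct: float = 0.0
    lyso: bool = False
    ether_prefix: str = ""  # "P-" plasmalogen / "O-" ether, if present


def library_search(
    spec: Spectrum,
    library: list[Spectrum],
    score_threshold: float = 0.7,
    min_matched: int = 2,
    frag_tol: float = 0.02,
) -> list[LibraryMatch]:
    """Modified-cosine search of one spectrum against a named library.

    Hits above both thresholds, sorted by score descending (ties by name).
    """
    if not library:
        return []
    hits = []
    for entry in library:
        res = modified_cosine(spec, entry, frag_tol)
        if res.score >= score_threshold and res.n_matched >= min_matched:
            hits.append(
                LibraryMatch(
                    feature_id=spec.feature_id,
                    compound_name=entry.name or entry.feature_id,
                    score=res.score,
                    n_matched=res.n_matched,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.compound_name))
    return hits


def _nearest_peak(spec: Spectrum, mz: float, window: float) -> float | None:
    if len(spec) == 0:
        return None
    diffs = np.abs(spec.mz - mz)
    k = int(np.argmin(diffs))
    return float(spec.mz[k]) if diffs[k] <= window else None


def propagate_analog(
    known: Spectrum,
    unknown: Spectrum,
    head_fragment_mzs: list[float],
    frag_tol: float = 0.02,
    search_window: float = 25.0,
    shift_tol: float = 0.005,
    dispersion_bound: float = 0.01,
    chain_unit: float = CH2,
    max_chain_units: int = 10,
) -> AnalogHypothesis:
    """Infer the modification relating an unknown spectrum to an annotated one.

    For each diagnostic head fragment of the known spectrum, the nearest
    unknown peak within ``search_window`` gives a shift (unknown - known);
    the median shift and the parent-ion delta then classify the pair:

    * ``chain_homolog`` — head fragments unmoved (|shift| <= shift_tol) and
      the parent delta a positive-integer multiple of the CH2 unit;
    * ``head_group_substitution`` — parent delta equals the fragment shift
      within shift_tol (the whole molecule moved with the head group);
    * ``mixed`` — a head shift plus a nonzero residual chain delta;
    * ``unclassified`` — fewer than two diagnostic fragments recovered, or
      fragment shifts disagreeing by more than ``dispersion_bound``.
    """
    parent_delta = unknown.precursor_mz - known.precursor_mz
    hyp = AnalogHypothesis(
        known_id=known.feature_id,
        unknown_id=unknown.feature_id,
        parent_delta=parent_delta,
    )
    # candidate shifts per diagnostic fragment: every unknown peak within
    # the search window proposes one; the shift supported by the most
    # fragments (ties -> smallest magnitude) is the dissociation-pattern
    # displacement, and each fragment contributes its nearest candidate
    candidates: list[list[float]] = []
    for frag in head_fragment_mzs:
        known_mz = _nearest_peak(known, frag, frag_tol)
        if known_mz is None:
            continue
        opts = [
            float(u - known_mz)
            for u in unknown.mz
            if abs(u - known_mz) <= search_window
        ]
        if opts:
            candidates.append(opts)
    shifts: list[float] = []
    if candidates:
        pool = sorted({s for opts in candidates for s in opts})
        best: tuple[int, float] | None = None
        for c in pool:
            support = sum(
                1 for opts in candidates
                if min(abs(s - c) for s in opts) <= dispersion_bound
            )
            if best is None or support > best[0] or (
                support == best[0] and abs(c) < abs(best[1])
            ):
                best = (support, c)
        centre = best[1]
        shifts = [min(opts, key=lambda s: abs(s - centre)) for opts in candidates]
    hyp.fragment_shifts = shifts
    if len(shifts) < 2:
        hyp.reason = f"only {len(shifts)} diagnostic fragments recovered (need 2)"
        return hyp
    shift = float(np.median(shifts))
    hyp.consistent_shift = shift
    hyp.shift_dispersion = float(np.max(np.abs(np.asarray(shifts) - shift)))
    hyp.chain_delta = parent_delta - shift
    if hyp.shift_dispersion > dispersion_bound:
        hyp.reason = (
            f"fragment shifts inconsistent (dispersion {hyp.shift_dispersion:.4f} Da)"
        )
        return hyp
    if abs(shift) <= shift_tol:
        for k in range(1, max_chain_units + 1):
            if abs(abs(parent_delta) - k * chain_unit) <= frag_tol:
                hyp.classification = "chain_homolog"
                return hyp
    if abs(parent_delta - shift) <= shift_tol:
        hyp.classification = "head_group_substitution"
        return hyp
    if abs(shift) > shift_tol and abs(hyp.chain_delta) > shift_tol:
        hyp.classification = "mixed"
        return hyp
    hyp.reason = "shift pattern matches no modification class"
    return hyp


_LIPID_RE = re.compile(
    r"^\s*(?P<lyso>lyso[- ])?\s*(?P<cls>[A-Za-z][A-Za-z0-9-]*(?: [A-Za-z0-9-]+)*?)"
    r"\s+(?P<ether>[PO]-)?(?P<c>\d+):(?P<d>\d+)\s*$",
    re.IGNORECASE,
)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse shorthand lipid names like ``lyso PC P-18:0`` or ``MAG 16:1``.

    Grammar: optional ``lyso`` prefix, class token(s), optional ``P-``/``O-``
    ether prefix, then carbons:double-bonds.
    """
    m = _LIPID_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse lipid name {name!r}")
    return LipidSpecies(
        name=name.strip(),
        lipid_class=m.group("cls"),
        n_carbons=int(m.group("c")),
        n_double_bonds=int(m.group("d")),
        lyso=m.group("lyso") is not None,
        ether_prefix=(m.group("ether") or "").upper(),
    )


def unsaturation_index(species: list[LipidSpecies]) -> dict[str, float]:
    """Abundance-weighted unsaturation index per lipid class and overall.

    UI_x = sum_y(pct_y * double_bonds_y) / 100 over the species y of class
    x, with percentages on whatever basis the caller chose (see
    :func:`abundance_percentages`). The ``"overall"`` key pools all species.
    """
    out: dict[str, float] = {}
    total = 0.0
    for sp in species:
        if sp.relative_abundance_pct < 0:
            raise ValueError(f"negative abundance for {sp.name!r}")
        contrib = sp.relative_abundance_pct * sp.n_double_bonds / 100.0
        out[sp.lipid_class] = out.get(sp.lipid_class, 0.0) + contrib
        total += contrib
    out["overall"] = total
    return out


def abundance_percentages(
    species: list[LipidSpecies],
    intensities: dict[str, float],
    basis: str = "total",
) -> list[LipidSpecies]:
    """Fill ``relative_abundance_pct`` from intensities.

    ``basis="total"`` expresses each species as percent of the summed
    intensity of all species in the set; ``basis="class"`` renormalizes
    within each lipid class to 100%.
    """
    if basis not in ("total", "class"):
        raise ValueError(f"unknown percentage basis {basis!r}")
    vals = {sp.name: float(intensities[sp.name]) for sp in species}
    if any(v < 0 for v in vals.values()):
        raise ValueError("negative intensity")
    out = []
    if basis == "total":
        denom = sum(vals.values())
        for sp in species:
            pct = 100.0 * vals[sp.name] / denom if denom > 0 else 0.0
            out.append(LipidSpecies(**{**sp.__dict__, "relative_abundance_pct": pct}))
    else:
        class_sum: dict[str, float] = {}
        for sp in species:
            class_sum[sp.lipid_class] = class_sum.get(sp.lipid_class, 0.0) + vals[sp.name]
        for sp in species:
            denom = class_sum[sp.lipid_class]
            pct = 100.0 * vals[sp.name] / denom if denom > 0 else 0.0
            out.append(LipidSpecies(**{**sp.__dict__, "relative_abundance_pct": pct}))
    return out


def load_worked_example() -> list[Spectrum]:
    """The packaged glycerophosphocholine analog example: the annotated
    lyso PC P-18:0 spectrum (m/z 508.3752) plus its two head-group analogs
    at m/z 507.3549 and 522.3905. Fragment m/z values follow the published
    diagnostic series and shifts; intensities are representative stand-ins
    (they do not affect mass-shift inference)."""
    from .io import read_mgf

    ref = resources.files("coralmet").joinpath("data/lysopc_worked_example.mgf")
    with resources.as_file(ref) as p:
        return read_mgf(p)


def load_diagnostic_fragments(path: str | Path | None = None) -> dict[str, list[float]]:
    """Load the diagnostic head-fragment series per compound class.

    The packaged default ships the glycerophosphocholine ion series
    (choline/phosphocholine fragments). The TSV has columns ``class`` and
    ``fragment_mzs`` (comma-separated m/z values).
    """
    if path is None:
        ref = resources.files("coralmet").joinpath("data/diagnostic_fragments.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return {
        str(row["class"]): [float(x) for x in str(row["fragment_mzs"]).split(",")]
        for _, row in df.iterrows()
    }
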