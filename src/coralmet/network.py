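"""Modified-cosine spectral similarity and molecular network construction.

The modified cosine allows a fragment pair to match either directly
(|mz_a - mz_b| <= tol) or offset by the precursor mass difference
(|mz_a - mz_b + dp| <= tol, dp = precursor_b - precursor_a), so that
spectra of structural analogs — same backbone, shifted substituent —
still score highly. Intensities are square-root transformed and each
spectrum's sqrt-intensity vector L2-normalized, so identical spectra score
exactly 1. A one-to-one peak matching is selected greedily by descending
pair score, with ties broken by smaller mass error, then lower peak index,
which makes the result deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import Spectrum

__all__ = [
    "SimilarityResult",
    "filter_peaks",
    "modified_cosine",
    "build_network",
    "connected_families",
    "write_graphml",
    "write_edge_list",
]


@dataclass
class SimilarityResult:
    score: float
    n_matched: int
    precursor_delta: float  # precursor_b - precursor_a
    matched_pairs: list[tuple[int, int, str]] = field(default_factory=list)
    # (index in a, index in b, "direct" | "shifted")


def filter_peaks(spec: Spectrum, min_intensity: float = 20000.0) -> Spectrum:
    """Drop fragment peaks below the minimum intensity (may leave an empty
    spectrum)."""
    keep = spec.intensities >= min_intensity
    return spec.with_peaks(spec.peaks[keep])


def _candidate_pairs(
    a: Spectrum, b: Spectrum, frag_tol: float, dp: float
) -> list[tuple[float, float, int, int, str]]:
    """All (score, |mass error|, i, j, kind) candidate peak pairs."""
    wa = np.sqrt(a.intensities)
    wb = np.sqrt(b.intensities)
    na = np.linalg.norm(wa)
    nb = np.linalg.norm(wb)
    if na == 0 or nb == 0:
        return []
    wa = wa / na
    wb = wb / nb
    pairs: list[tuple[float, float, int, int, str]] = []
    offsets = [("direct", 0.0)]
    if abs(dp) > frag_tol:
        offsets.append(("shifted", dp))
    for kind, off in offsets:
        # peak j of b matches peak i of a when mz_b ~ mz_a + off
        for i, mz_i in enumerate(a.mz):
            lo = np.searchsorted(b.mz, mz_i + off - frag_tol, side="left")
            hi = np.searchsorted(b.mz, mz_i + off + frag_tol, side="right")
            for j in range(lo, hi):
                err = abs(b.mz[j] - mz_i - off)
                pairs.append((float(wa[i] * wb[j]), err, i, j, kind))
    return pairs


def modified_cosine(
    a: Spectrum, b: Spectrum, frag_tol: float = 0.02
) -> SimilarityResult:
    """Modified-cosine similarity between two spectra.

    Returns score in [0, 1], the matched-peak count and the matched pairs.
    Empty spectra give score 0. The score is symmetric in its arguments and
    invariant to uniform intensity rescaling of either spectrum.
    """
    dp = b.precursor_mz - a.precursor_mz
    if len(a) == 0 or len(b) == 0:
        return SimilarityResult(0.0, 0, dp)
    pairs = _candidate_pairs(a, b, frag_tol, dp)
    # greedy: descending score, then smaller mass error, then lower indices
    pairs.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[int, int, str]] = []
    score = 0.0
    for s, _err, i, j, kind in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j, kind))
        score += s
    return SimilarityResult(
        score=float(min(score, 1.0)),
        n_matched=len(matched),
        precursor_delta=dp,
        matched_pairs=matched,
    )


def build_network(
    spectra: list[Spectrum],
    score_threshold: float = 0.7,
    min_matched: int = 2,
    topk: int = 10,
    max_component: int = 100,
    frag_tol: float = 0.02,
    min_intensity: float = 0.0,
) -> nx.Graph:
    """All-vs-all modified-cosine molecular network.

    Edges require score >= ``score_threshold`` and at least ``min_matched``
    matched peaks; each node keeps an edge only if it is within the top-k
    edges of both endpoints; components larger than ``max_component`` are
    pruned by removing their lowest-score edges first.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to build a network")
    if min_intensity > 0:
        spectra = [filter_peaks(s, min_intensity) for s in spectra]
    g = nx.Graph()
    for s in spectra:
        g.add_node(s.feature_id, spectrum=s, precursor_mz=s.precursor_mz)
    candidates = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            res = modified_cosine(spectra[i], spectra[j], frag_tol)
            if res.score >= score_threshold and res.n_matched >= min_matched:
                candidates.append((spectra[i].feature_id, spectra[j].feature_id, res))

    # mutual top-k filter
    per_node: dict[str, list[tuple[float, str]]] = {}
    for u, v, res in candidates:
        per_node.setdefault(u, []).append((res.score, v))
        per_node.setdefault(v, []).append((res.score, u))
    top: dict[str, set[str]] = {}
    for node, lst in per_node.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
        top[node] = {other for _, other in lst[:topk]}
    for u, v, res in candidates:
        if v in top.get(u, set()) and u in top.get(v, set()):
            g.add_edge(
                u, v,
                cosine=res.score,
                matched_peaks=res.n_matched,
                delta_mz=res.precursor_delta,
            )

    # component-size cap: drop weakest edges of oversized components
    changed = True
    while changed:
        changed = False
        for comp in list(nx.connected_components(g)):
            if len(comp) <= max_component:
                continue
            sub_edges = [
                (d["cosine"], u, v) for u, v, d in g.subgraph(comp).edges(data=True)
            ]
            sub_edges.sort()
            g.remove_edge(sub_edges[0][1], sub_edges[0][2])
            changed = True
    return g


def connected_families(net: nx.Graph) -> list[list[str]]:
    """Connected components ("molecular families"), each sorted by member
    id, ordered by smallest member id."""
    comps = [sorted(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: c[0])
    return comps


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    g = net.copy()
    for _, data in g.nodes(data=True):
        data.pop("spectrum", None)  # Spectrum objects are not GraphML types
    nx.write_graphml(g, str(path))


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    lines = ["source\ttarget\tcosine\tmatched_peaks\tdelta_mz"]
    for u, v, d in sorted(net.edges(data=True)):
        lines.append(
            f"{u}\t{v}\t{d['cosine']:.4f}\t{d['matched_peaks']}\t{d['delta_mz']:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
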