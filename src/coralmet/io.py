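"""Reading and writing MS/MS spectra (MGF) and feature quantification tables.

The MGF dialect is the GNPS/FBMN style produced by MZmine exports:
``FEATURE_ID=`` (or ``SCANS=``) identifies the LC feature, ``PEPMASS=`` the
precursor m/z, ``CHARGE=1+`` the charge, and ``RTINSECONDS=`` the retention
time. The quantification table is the MZmine CSV export with columns
``row ID``, ``row m/z``, ``row retention time`` followed by one intensity
column per sample (an optional `` Peak area`` suffix is stripped). Sample
groups come from a sidecar tab-separated metadata file with columns
``sample_id`` and ``group`` (values ``A``, ``B``, ``QC`` or ``blank``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _pyteomics_mgf

__all__ = [
    "Spectrum",
    "FeatureTable",
    "MgfError",
    "read_mgf",
    "write_mgf",
    "read_quant_table",
    "write_quant_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "match_spectra_to_table",
]

SAMPLE_GROUPS = ("A", "B", "QC", "blank")


class MgfError(ValueError):
    """Raised for malformed MGF records or spectra."""


@dataclass(frozen=True)
class Spectrum:
    """One consensus MS/MS spectrum attached to an LC feature.

    Parameters
    ----------
    feature_id:
        Identifier linking the spectrum to a quantification-table row.
    precursor_mz:
        Precursor (parent ion) m/z in Thomson.
    peaks:
        Array of shape (n, 2) with columns (fragment m/z, intensity),
        sorted ascending by m/z; intensities are non-negative counts.
    charge:
        Precursor charge state (positive mode, default 1).
    retention_time:
        Retention time in minutes, or ``None`` if unknown.
    name:
        Optional compound name (library spectra).
    """

    feature_id: str
    precursor_mz: float
    peaks: np.ndarray
    charge: int = 1
    retention_time: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size and not np.all(np.diff(peaks[:, 0]) >= 0):
            order = np.argsort(peaks[:, 0], kind="stable")
            peaks = peaks[order]
        peaks.setflags(write=False)
        object.__setattr__(self, "peaks", peaks)
        if not self.feature_id:
            raise MgfError("feature_id must be non-empty")
        if not (self.precursor_mz > 0):
            raise MgfError(
                f"feature {self.feature_id!r}: precursor m/z must be positive"
            )
        if peaks.size and (peaks[:, 1] < 0).any():
            raise MgfError(f"feature {self.feature_id!r}: negative peak intensity")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensities(self) -> np.ndarray:
        return self.peaks[:, 1]

    def __len__(self) -> int:
        return self.peaks.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.feature_id == other.feature_id
            and self.precursor_mz == other.precursor_mz
            and self.charge == other.charge
            and self.retention_time == other.retention_time
            and self.name == other.name
            and self.peaks.shape == other.peaks.shape
            and bool(np.all(self.peaks == other.peaks))
        )

    def with_peaks(self, peaks: np.ndarray) -> "Spectrum":
        return replace(self, peaks=peaks)


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix with feature m/z, RT and sample groups.

    ``intensities`` is a DataFrame indexed by feature id with one column per
    sample; ``feature_mz``/``feature_rt`` are Series on the same index and
    ``sample_group`` a Series on the sample columns with values from
    ``SAMPLE_GROUPS`` (or ``None`` when no metadata was supplied).
    """

    intensities: pd.DataFrame
    feature_mz: pd.Series
    feature_rt: pd.Series
    sample_group: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities in feature table")
        for s in (self.feature_mz, self.feature_rt):
            if not s.index.equals(idx):
                raise ValueError("feature metadata index does not match matrix")
        if self.sample_group is None:
            self.sample_group = pd.Series(
                [None] * self.intensities.shape[1], index=self.intensities.columns
            )
        elif not self.sample_group.index.equals(self.intensities.columns):
            self.sample_group = self.sample_group.reindex(self.intensities.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.sample_group.index[self.sample_group == group])

    def subset_features(self, ids: Sequence[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(
            intensities=self.intensities.loc[ids].copy(),
            feature_mz=self.feature_mz.loc[ids].copy(),
            feature_rt=self.feature_rt.loc[ids].copy(),
            sample_group=self.sample_group.copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            intensities=self.intensities.copy(),
            feature_mz=self.feature_mz.copy(),
            feature_rt=self.feature_rt.copy(),
            sample_group=self.sample_group.copy(),
        )


# ---------------------------------------------------------------------------
# MGF


def _spectrum_from_record(index: int, record: dict) -> Spectrum:
    params = record.get("params", {})
    if "pepmass" not in params or params["pepmass"] is None:
        raise MgfError(f"MGF record {index}: missing PEPMASS")
    pepmass = params["pepmass"]
    precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
    fid = params.get("feature_id") or params.get("scans")
    if fid is None:
        raise MgfError(f"MGF record {index}: missing FEATURE_ID/SCANS")
    charge = 1
    if params.get("charge"):
        charge = int(params["charge"][0])
    rt = None
    if "rtinseconds" in params:
        # minutes kept to 1e-6 so the seconds<->minutes conversion round-trips
        rt = round(float(params["rtinseconds"]) / 60.0, 6)
    name = params.get("name")
    mz = np.asarray(record.get("m/z array", []), dtype=float)
    inten = np.asarray(record.get("intensity array", []), dtype=float)
    if (~np.isfinite(mz)).any() or (~np.isfinite(inten)).any():
        raise MgfError(f"MGF record {index}: non-finite peak values")
    keep = inten > 0
    peaks = np.column_stack([mz[keep], inten[keep]]) if mz.size else np.empty((0, 2))
    try:
        return Spectrum(
            feature_id=str(fid),
            precursor_mz=precursor,
            peaks=peaks,
            charge=charge,
            retention_time=rt,
            name=name,
        )
    except MgfError as exc:
        raise MgfError(f"MGF record {index}: {exc}") from exc


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read a GNPS-style MGF file into a list of :class:`Spectrum`.

    Records are 1-indexed in error messages. Zero-intensity peaks are
    dropped and peaks re-sorted ascending by m/z.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    with _pyteomics_mgf.MGF(str(path), convert_arrays=1) as reader:
        for index, record in enumerate(reader, start=1):
            try:
                spectra.append(_spectrum_from_record(index, record))
            except MgfError:
                raise
            except Exception as exc:  # malformed numbers etc.
                raise MgfError(f"MGF record {index}: malformed record ({exc})") from exc
    seen: set[str] = set()
    for spec in spectra:
        if spec.feature_id in seen:
            raise MgfError(f"duplicate feature id {spec.feature_id!r} in {path}")
        seen.add(spec.feature_id)
    return spectra


def _fmt(x: float) -> str:
    # repr gives the shortest string that round-trips the float exactly
    return repr(float(x))


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as a GNPS-FBMN style MGF file (deterministic field order)."""
    lines: list[str] = []
    for spec in spectra:
        if not np.all(np.isfinite(spec.peaks)):
            raise MgfError(f"feature {spec.feature_id!r}: non-finite peak values")
        lines.append("BEGIN IONS")
        lines.append(f"FEATURE_ID={spec.feature_id}")
        lines.append(f"PEPMASS={_fmt(spec.precursor_mz)}")
        sign = "+" if spec.charge >= 0 else "-"
        lines.append(f"CHARGE={abs(spec.charge)}{sign}")
        if spec.retention_time is not None:
            lines.append(f"RTINSECONDS={_fmt(spec.retention_time * 60.0)}")
        if spec.name is not None:
            lines.append(f"NAME={spec.name}")
        for mz, inten in spec.peaks:
            lines.append(f"{_fmt(mz)} {_fmt(inten)}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Quantification table and sample metadata

_QUANT_ID = "row ID"
_QUANT_MZ = "row m/z"
_QUANT_RT = "row retention time"


def read_quant_table(
    path: str | Path, metadata_path: str | Path | None = None
) -> FeatureTable:
    """Read an MZmine-style feature quantification CSV.

    Sample columns may carry the MZmine `` Peak area`` suffix, which is
    stripped. When ``metadata_path`` is given, sample groups are joined from
    it; samples missing from the metadata raise an error.
    """
    df = pd.read_csv(path)
    df = df.loc[:, [c for c in df.columns if not c.startswith("Unnamed")]]
    for col in (_QUANT_ID, _QUANT_MZ, _QUANT_RT):
        if col not in df.columns:
            raise ValueError(f"quant table missing column {col!r}")
    ids = df[_QUANT_ID].astype(str)
    if ids.duplicated().any():
        raise ValueError(
            f"duplicate feature ids: {ids[ids.duplicated()].unique().tolist()}"
        )
    sample_cols = [c for c in df.columns if c not in (_QUANT_ID, _QUANT_MZ, _QUANT_RT)]
    matrix = df[sample_cols].astype(float)
    matrix.columns = [c.removesuffix(" Peak area").strip() for c in sample_cols]
    matrix.index = pd.Index(ids.to_numpy(), name=None)
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative intensity in quant table")
    groups = None
    if metadata_path is not None:
        meta = read_sample_metadata(metadata_path)
        missing = [s for s in matrix.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        groups = meta.loc[matrix.columns]
    return FeatureTable(
        intensities=matrix,
        feature_mz=pd.Series(df[_QUANT_MZ].to_numpy(float), index=ids, name="mz"),
        feature_rt=pd.Series(df[_QUANT_RT].to_numpy(float), index=ids, name="rt"),
        sample_group=groups,
    )


def write_quant_table(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable in the MZmine export dialect read by read_quant_table."""
    out = pd.DataFrame(
        {
            _QUANT_ID: table.feature_ids,
            _QUANT_MZ: table.feature_mz.to_numpy(),
            _QUANT_RT: table.feature_rt.to_numpy(),
        }
    )
    for sample in table.sample_ids:
        out[sample] = table.intensities[sample].to_numpy()
    out.to_csv(path, index=False)


def read_sample_metadata(path: str | Path) -> pd.Series:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("sample metadata needs 'sample_id' and 'group' columns")
    bad = set(meta["group"]) - set(SAMPLE_GROUPS)
    if bad:
        raise ValueError(f"unknown sample groups {sorted(bad)}; expected {SAMPLE_GROUPS}")
    return pd.Series(
        meta["group"].to_numpy(), index=meta["sample_id"].to_numpy(), name="group"
    )


def write_sample_metadata(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def match_spectra_to_table(
    spectra: Sequence[Spectrum], table: FeatureTable
) -> dict[str, Spectrum]:
    """Bind spectra to quantification rows by feature id.

    Returns a feature_id -> Spectrum mapping restricted to ids present in the
    table; raises if any spectrum has no table row or vice versa (orphan ids
    are listed in the error).
    """
    by_id = {s.feature_id: s for s in spectra}
    table_ids = set(table.feature_ids)
    orphan_spectra = sorted(set(by_id) - table_ids)
    orphan_rows = sorted(table_ids - set(by_id))
    if orphan_spectra or orphan_rows:
        raise ValueError(
            "spectra/table id mismatch: "
            f"spectra without rows {orphan_spectra}; rows without spectra {orphan_rows}"
        )
    return {fid: by_id[fid] for fid in table.feature_ids}
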