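"""Domain types, file readers/writers and run configuration.

The central object of the pipeline is the :class:`IntensityMatrix`, a
proteins x samples table of DIA protein-group quantitation values with
explicit missing cells (``NaN``).  Sample annotations (liver of origin,
perfusion timepoint, acquisition batch) and per-liver clinical labels
live in :class:`CohortMetadata`.  All on-disk formats are tab-separated
UTF-8 with a single header row; result tables carry a commented header
block recording the run configuration so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bileflow")

#: Closed set of perfusion timepoints: 30 min NMP, 150 min NMP (viability
#: assessment) and end of perfusion (transplanted livers only).
TIMEPOINTS = ("T30", "T150", "End")

#: Tokens mapped to missing on read, besides the empty cell.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan"})


class BileflowError(ValueError):
    """Base class for input-contract violations."""


# ---------------------------------------------------------------------------
# IntensityMatrix
# ---------------------------------------------------------------------------

_VALID_SCALES = ("raw", "log2", "z")


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity table with explicit missing cells.

    Parameters
    ----------
    data:
        DataFrame indexed by protein id, columns are sample ids, values
        float with ``NaN`` marking unquantified cells.
    scale:
        ``"raw"`` (linear intensities, strictly positive where present),
        ``"log2"`` or ``"z"`` (row z-scores).
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise BileflowError(
                f"unknown scale {self.scale!r}; expected one of {_VALID_SCALES}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise BileflowError(f"duplicate protein ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise BileflowError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)
        if self.scale == "raw":
            vals = self.data.to_numpy()
            bad = (vals <= 0) & ~np.isnan(vals)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise BileflowError(
                    "raw-scale intensities must be strictly positive where "
                    f"present; offending cell ({self.data.index[r]!r}, "
                    f"{self.data.columns[c]!r}) = {vals[r, c]}"
                )

    # -- convenience accessors ------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), self.scale)

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise BileflowError(f"unknown sample ids: {missing}")
        return IntensityMatrix(self.data.loc[:, list(sample_ids)].copy(), self.scale)

    def subset_proteins(self, protein_ids: Sequence[str]) -> "IntensityMatrix":
        missing = [p for p in protein_ids if p not in self.data.index]
        if missing:
            raise BileflowError(f"unknown protein ids: {missing}")
        return IntensityMatrix(self.data.loc[list(protein_ids)].copy(), self.scale)

    def equals(self, other: "IntensityMatrix") -> bool:
        return self.scale == other.scale and self.data.equals(other.data)


def read_intensity_matrix(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    scale: str = "raw",
    zero_is_missing: bool = False,
) -> IntensityMatrix:
    """Read a wide TSV intensity matrix (first column protein id).

    ``missing_tokens`` (plus, optionally, ``"0"`` when ``zero_is_missing``)
    become explicit missing cells.  Duplicate protein ids and ragged rows
    are hard errors.
    """
    path = Path(path)
    tokens = set(missing_tokens)
    if zero_is_missing:
        tokens |= {"0", "0.0"}
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise BileflowError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_cols = len(header)
    sample_ids = header[1:]
    rows: dict[str, list[float]] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise BileflowError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {n_cols})"
            )
        pid = parts[0]
        if pid in rows:
            raise BileflowError(f"{path}:{lineno}: duplicate protein id {pid!r}")
        vals = []
        for cell in parts[1:]:
            if cell.strip() in tokens:
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise BileflowError(
                        f"{path}:{lineno}: unparseable value {cell!r}"
                    ) from exc
        rows[pid] = vals
    data = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    data.index.name = "protein"
    return IntensityMatrix(data, scale=scale)


def write_intensity_matrix(
    matrix: IntensityMatrix,
    path: str | Path,
    header_comments: Mapping[str, object] | None = None,
) -> None:
    """Write a wide TSV, missing cells as "NA", optional ``# key=value`` header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header_comments:
            for key, val in header_comments.items():
                fh.write(f"# {key}={val}\n")
        fh.write("# scale=" + matrix.scale + "\n")
        fh.write("protein\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for pid, row in matrix.data.iterrows():
            cells = ["NA" if pd.isna(v) else format(v, ".10g") for v in row]
            fh.write(str(pid) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# CohortMetadata
# ---------------------------------------------------------------------------

_VIABILITY_CLASSES = ("high", "low", "unset")
_BDI_CLASSES = ("high", "low", "ungradable", "unset")


@dataclass
class CohortMetadata:
    """Per-sample and per-liver annotations.

    ``samples`` is indexed by sample id with columns ``liver_id``,
    ``timepoint`` and ``batch``; ``livers`` is indexed by liver id with
    columns ``transplanted`` (bool), ``viability_class`` and ``bdi_class``.
    """

    samples: pd.DataFrame
    livers: pd.DataFrame

    def __post_init__(self) -> None:
        required_s = {"liver_id", "timepoint", "batch"}
        if not required_s.issubset(self.samples.columns):
            raise BileflowError(
                f"sample table must have columns {sorted(required_s)}"
            )
        required_l = {"transplanted", "viability_class", "bdi_class"}
        if not required_l.issubset(self.livers.columns):
            raise BileflowError(
                f"liver table must have columns {sorted(required_l)}"
            )
        bad_tp = sorted(set(self.samples["timepoint"]) - set(TIMEPOINTS))
        if bad_tp:
            raise BileflowError(
                f"unknown timepoint labels {bad_tp}; allowed: {list(TIMEPOINTS)}"
            )
        unknown = sorted(
            set(self.samples["liver_id"]) - set(self.livers.index)
        )
        if unknown:
            raise BileflowError(f"samples reference unknown livers: {unknown}")
        pair = self.samples[["liver_id", "timepoint"]]
        dup = pair[pair.duplicated()]
        if len(dup):
            raise BileflowError(
                "duplicate (liver, timepoint) pairs: "
                + ", ".join(f"({r.liver_id}, {r.timepoint})" for r in dup.itertuples())
            )
        for col, allowed in (
            ("viability_class", _VIABILITY_CLASSES),
            ("bdi_class", _BDI_CLASSES),
        ):
            bad = sorted(set(self.livers[col].dropna()) - set(allowed))
            if bad:
                raise BileflowError(f"unknown {col} labels {bad}; allowed {allowed}")

    def samples_at(self, timepoint: str) -> pd.DataFrame:
        if timepoint not in TIMEPOINTS:
            raise BileflowError(
                f"unknown timepoint {timepoint!r}; allowed: {list(TIMEPOINTS)}"
            )
        return self.samples[self.samples["timepoint"] == timepoint]

    def liver_of(self, sample_id: str) -> str:
        return str(self.samples.loc[sample_id, "liver_id"])

    def sample_labels(self, sample_ids: Sequence[str], liver_column: str) -> pd.Series:
        """Per-sample labels pulled from a liver-level column."""
        livers = self.samples.loc[list(sample_ids), "liver_id"]
        return pd.Series(
            self.livers.loc[livers, liver_column].to_numpy(),
            index=list(sample_ids),
            name=liver_column,
        )


def read_metadata(sample_path: str | Path, liver_path: str | Path) -> CohortMetadata:
    """Read sample and liver annotation TSVs into a validated CohortMetadata."""
    samples = pd.read_csv(sample_path, sep="\t", index_col=0, comment="#", dtype=str)
    livers = pd.read_csv(liver_path, sep="\t", index_col=0, comment="#")
    if "transplanted" in livers.columns:
        livers["transplanted"] = livers["transplanted"].astype(bool)
    return CohortMetadata(samples, livers)


def write_metadata(meta: CohortMetadata, sample_path: str | Path, liver_path: str | Path) -> None:
    meta.samples.to_csv(sample_path, sep="\t", index_label="sample_id")
    meta.livers.to_csv(liver_path, sep="\t", index_label="liver_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, then member ids.

    Duplicate members within a set are deduplicated; sets without members
    are dropped with a logged warning.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 2:
                raise BileflowError(
                    f"{path}:{lineno}: GMT line needs at least name and description"
                )
            name = parts[0]
            members = {m for m in parts[2:] if m}
            if not members:
                logger.warning("GMT set %r (line %d) has no members; dropped", name, lineno)
                continue
            if name in sets:
                raise BileflowError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write(name + "\t-\t" + "\t".join(sorted(set(members))) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Thresholds, parameters and seed shared across pipeline stages."""

    presence_threshold: float = 0.40
    fold_change_threshold: float = 2.0
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    imputation_width: float = 0.3
    imputation_downshift: float = 1.8
    imputation_scope: str = "per_sample"
    n_permutations: int = 250
    kmeans_k: int = 4
    kmeans_n_init: int = 10
    rin_threshold: float = 7.0
    viability_point_threshold: int = 5
    top_k: int = 30
    seed: int = 0
    criteria_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("presence_threshold",):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise BileflowError(f"{name} must be in (0, 1], got {v}")
        if self.n_permutations < 1:
            raise BileflowError("n_permutations must be >= 1")
        if self.imputation_width <= 0 or self.imputation_downshift < 0:
            raise BileflowError("invalid imputation parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise BileflowError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def header_block(self) -> dict[str, object]:
        """key=value pairs written into every result table header."""
        return dataclasses.asdict(self)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    header_comments: Mapping[str, object] | None = None,
    index_label: str | None = None,
) -> None:
    """Write a result table as TSV with a commented header block."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for key, val in (header_comments or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)
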