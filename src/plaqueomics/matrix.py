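"""Protein-group intensity matrices: I/O, QC filters, and normalization.

The central container is :class:`IntensityMatrix`, a log2-scale
proteins-by-samples matrix (DIA-NN ``pg_matrix`` orientation) with
explicit missingness (NaN) and per-sample metadata describing the paired
laser-capture design: each ``pair_id`` links one plaque capture to its
adjacent non-plaque control within a model-by-age stratum.

All downstream stages (differential abundance, temporal profiling,
network analysis) consume this container; log2 is the single internal
scale, so every fold change is a difference of stored values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "ContaminantList",
    "DEFAULT_CONTAMINANT_PATTERNS",
    "read_matrix",
    "write_matrix",
    "read_contaminant_list",
    "filter_contaminants",
    "filter_min_detection",
    "median_normalize",
    "extract_tracer",
]

#: Region labels used in sample metadata.
PLAQUE = "plaque"
NONPLAQUE = "nonplaque"

METADATA_COLUMNS = ["sample_id", "model", "age_months", "region", "pair_id", "replicate"]

#: Shipped default contaminant patterns (substring, case-insensitive):
#: keratins, trypsin, and the ``CON__`` prefix convention of common
#: contaminant FASTA databases.
DEFAULT_CONTAMINANT_PATTERNS = ("KRT", "TRYP", "CON__", "ALBU_BOVIN", "CAS1_BOVIN")


@dataclass
class IntensityMatrix:
    """Log2 protein intensities with paired sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample id.
        Missing observations are NaN; all present values must be finite.
    samples
        DataFrame indexed by sample id with columns ``model``,
        ``age_months``, ``region`` (``plaque``/``nonplaque``),
        ``pair_id`` and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check the container invariants, raising ``ValueError`` on violation."""
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in matrix")
        missing_meta = set(self.values.columns) - set(self.samples.index)
        if missing_meta:
            raise ValueError(f"samples absent from metadata: {sorted(missing_meta)[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite (infinite) intensities present")
        # every pair id must occur as exactly one plaque + one nonplaque
        # sample within the same model x age stratum
        meta = self.samples.loc[list(self.values.columns)]
        for (model, age, pair), grp in meta.groupby(["model", "age_months", "pair_id"]):
            regions = sorted(grp["region"].tolist())
            if regions != [NONPLAQUE, PLAQUE]:
                raise ValueError(
                    f"pair {pair!r} in stratum {model}:{age} has regions {regions}; "
                    "expected exactly one plaque and one nonplaque sample"
                )

    # ------------------------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (True where observed)."""
        return self.values.notna()

    def meta(self) -> pd.DataFrame:
        """Metadata aligned to the matrix column order."""
        return self.samples.loc[list(self.values.columns)]

    def strata(self) -> list[tuple[str, object]]:
        """Sorted (model, age) strata present in the metadata."""
        meta = self.meta()
        return sorted(
            {(m, a) for m, a in zip(meta["model"], meta["age_months"])},
            key=lambda t: (str(t[0]), float(t[1])),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        keep = [s for s in self.values.columns if s in set(sample_ids)]
        return IntensityMatrix(self.values[keep].copy(), self.samples.loc[keep].copy())

    def subset_proteins(self, protein_ids: Sequence[str]) -> "IntensityMatrix":
        keep = [p for p in self.values.index if p in set(protein_ids)]
        return IntensityMatrix(self.values.loc[keep].copy(), self.samples.copy())

    def stratum(self, model: str, age: object) -> "IntensityMatrix":
        meta = self.meta()
        sel = meta.index[(meta["model"] == model) & (meta["age_months"] == age)]
        return self.subset_samples(list(sel))

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.samples.copy())


@dataclass
class ContaminantList:
    """Exact ids and substring patterns flagging contaminant protein groups.

    Matching is case-insensitive substring containment, so pattern
    ``KRT`` removes ``KRT10_HUMAN`` and also ``AKRT1``.
    """

    patterns: tuple[str, ...] = DEFAULT_CONTAMINANT_PATTERNS

    def __post_init__(self) -> None:
        pats = tuple(p.strip() for p in self.patterns if p.strip())
        if not pats:
            raise ValueError("contaminant list must contain at least one pattern")
        self.patterns = pats

    def matches(self, protein_id: str) -> bool:
        pid = protein_id.upper()
        return any(p.upper() in pid for p in self.patterns)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA", "NAN"}


def read_matrix(matrix_path: str | Path, metadata_path: str | Path) -> IntensityMatrix:
    """Read a protein-group matrix TSV plus its sample-metadata TSV.

    The matrix file has protein ids in the first column and one column
    per sample; empty cells and the tokens ``NA``/``NaN`` are missing.
    The metadata file may carry a ``# scale=raw`` comment header, in
    which case intensities are log2-transformed on read (zeros and
    negatives become missing); the default scale is log2.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    values = pd.read_csv(
        matrix_path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    values = values.apply(
        lambda col: col.map(
            lambda c: np.nan if c.strip().upper() in _MISSING_TOKENS else float(c)
        )
    ).astype(float)

    scale = "log2"
    with open(metadata_path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("scale="):
                    scale = stripped.split("=", 1)[1].strip().lower()
            else:
                header_lines.append(line)
    samples = pd.read_csv(metadata_path, sep="\t", comment="#")
    missing_cols = set(METADATA_COLUMNS) - set(samples.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    samples = samples.set_index("sample_id")

    unknown = set(values.columns) - set(samples.index)
    if unknown:
        raise ValueError(f"samples in matrix absent from metadata: {sorted(unknown)[:5]}")

    if scale == "raw":
        with np.errstate(divide="ignore", invalid="ignore"):
            arr = values.to_numpy(dtype=float)
            arr = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    elif scale != "log2":
        raise ValueError(f"unknown scale flag: {scale!r}")

    return IntensityMatrix(values, samples)


def write_matrix(
    m: IntensityMatrix, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write matrix + metadata TSVs (missing cells as empty strings, log2 scale)."""
    out = m.values.copy()
    out.index.name = "protein_id"
    # fixed-precision text keeps round trips stable to 6 significant digits
    out.to_csv(matrix_path, sep="\t", na_rep="", float_format="%.6g")
    meta = m.meta().reset_index()
    meta.columns = ["sample_id"] + list(meta.columns[1:])
    with open(metadata_path, "w") as fh:
        fh.write("# scale=log2\n")
        meta[METADATA_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_contaminant_list(path: str | Path) -> ContaminantList:
    """Read one pattern per line; ``#`` starts a comment."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append(line)
    return ContaminantList(tuple(patterns))


# ----------------------------------------------------------------------
# QC filters and normalization
# ----------------------------------------------------------------------


def filter_contaminants(
    m: IntensityMatrix, contaminants: ContaminantList | None = None
) -> IntensityMatrix:
    """Drop protein groups matching any contaminant id or pattern.

    Row order of the survivors is preserved. Returns an empty matrix
    (with a warning) if everything matches.
    """
    contaminants = contaminants or ContaminantList()
    keep = [p for p in m.values.index if not contaminants.matches(str(p))]
    n_removed = m.n_proteins - len(keep)
    if not keep:
        warnings.warn("contaminant filter removed every protein", stacklevel=2)
    result = IntensityMatrix(m.values.loc[keep].copy(), m.samples.copy())
    result.values.attrs["n_contaminants_removed"] = n_removed
    return result


def filter_min_detection(m: IntensityMatrix, min_samples: int = 3) -> IntensityMatrix:
    """Drop proteins detected in fewer than ``min_samples`` samples.

    A protein with exactly ``min_samples`` detections is retained.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    n_det = m.values.notna().sum(axis=1)
    keep = m.values.index[n_det >= min_samples]
    result = IntensityMatrix(m.values.loc[keep].copy(), m.samples.copy())
    result.values.attrs["n_low_detection_removed"] = int(m.n_proteins - len(keep))
    return result


def median_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Equalize per-sample medians by an additive log2 shift.

    Every sample's median of observed values is shifted to the grand
    median of the pre-normalization sample medians, preserving the
    overall intensity scale. Missing cells stay missing.
    """
    medians = m.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"samples with no observed values: {bad[:5]}")
    target = float(np.median(medians.to_numpy()))
    shifted = m.values.sub(medians - target, axis=1)
    return IntensityMatrix(shifted, m.samples.copy())


def extract_tracer(m: IntensityMatrix, tracer_id: str) -> pd.DataFrame:
    """Return the tracer protein's observed values with sample metadata.

    Used for QC of the capture design: the amyloid-beta tracer peptide
    should be plaque-enriched at every age and rise with age in plaques.
    """
    if tracer_id not in m.values.index:
        raise KeyError(f"tracer {tracer_id!r} not present in matrix")
    series = m.values.loc[tracer_id]
    out = m.meta().copy()
    out["intensity"] = series
    return out[["model", "age_months", "region", "pair_id", "intensity"]]
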