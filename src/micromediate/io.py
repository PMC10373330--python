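"""Reading, writing and assembly of taxa tables and sample metadata.

The canonical in-memory objects are :class:`TaxaTable` (samples x taxa
relative abundances, rows on the unit simplex), :class:`SampleMetadata`
(binary exposure ``R``, continuous outcome ``Y``, numeric covariates
``X``) and their aligned combination :class:`StudyData`, which every
downstream estimator consumes.

Exposure coding follows the convention ``R = 1`` for the reference group
and ``R = 0`` for the comparison group; the sign of all disparity
measures depends on it, so file readers take the reference label
explicitly rather than guessing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxaTable",
    "SampleMetadata",
    "StudyData",
    "read_taxa_table",
    "read_metadata",
    "assemble_study",
    "write_results",
]

_ROW_SUM_TOL = 1e-8


@dataclasses.dataclass
class TaxaTable:
    """Samples x taxa relative-abundance matrix.

    ``values[i, j]`` is the relative abundance of taxon ``j`` in sample
    ``i``; every row sums to one (within 1e-8) and all entries are
    non-negative.
    """

    sample_ids: list
    taxon_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.taxon_ids = list(self.taxon_ids)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")
        if np.any(self.values < 0):
            raise ValueError("negative abundances")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite abundances")
        row_sums = self.values.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > _ROW_SUM_TOL):
            bad = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"rows must sum to 1 (sample {self.sample_ids[bad]!r} "
                f"sums to {row_sums[bad]:.6g}); normalize first"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample exposure, outcome and covariates.

    ``frame`` is indexed by sample id; the named exposure column is 0/1
    (1 = reference group), the outcome column is continuous and the
    covariate columns are numeric (categoricals pre-encoded).
    """

    frame: pd.DataFrame
    exposure: str = "exposure"
    outcome: str = "outcome"
    covariates: Sequence[str] = ()

    def __post_init__(self):
        self.covariates = list(self.covariates)
        cols = [self.exposure, self.outcome, *self.covariates]
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        sub = self.frame[cols]
        if sub.isna().any().any():
            bad = sub.index[sub.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values in metadata for samples {bad}")
        r = np.asarray(self.frame[self.exposure])
        if not np.isin(r, [0, 1]).all():
            raise ValueError(
                f"exposure column {self.exposure!r} must be coded 0/1 "
                f"(1 = reference group); got values {sorted(set(r))}"
            )
        y = np.asarray(self.frame[self.outcome], dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("outcome contains non-finite values")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def r(self) -> np.ndarray:
        return np.asarray(self.frame[self.exposure], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.frame[self.outcome], dtype=float)

    @property
    def x(self) -> np.ndarray:
        """Covariate matrix of shape (n_samples, K); K may be zero."""
        return np.asarray(self.frame[self.covariates], dtype=float).reshape(
            len(self.frame), len(self.covariates)
        )


@dataclasses.dataclass
class StudyData:
    """A taxa table and metadata aligned on the same ordered samples."""

    taxa: TaxaTable
    meta: SampleMetadata
    n_dropped: int = 0

    def __post_init__(self):
        if self.taxa.sample_ids != self.meta.sample_ids:
            raise ValueError("taxa and metadata sample ids are not aligned")
        r = self.meta.r
        if (r == 1).sum() < 2 or (r == 0).sum() < 2:
            raise ValueError("each exposure group needs at least 2 samples")

    # convenience accessors used throughout the estimators
    @property
    def m(self) -> np.ndarray:
        return self.taxa.values

    @property
    def r(self) -> np.ndarray:
        return self.meta.r

    @property
    def y(self) -> np.ndarray:
        return self.meta.y

    @property
    def x(self) -> np.ndarray:
        return self.meta.x

    @property
    def sample_ids(self) -> list:
        return self.taxa.sample_ids

    @property
    def taxon_ids(self) -> list:
        return self.taxa.taxon_ids

    @property
    def n_samples(self) -> int:
        return self.taxa.n_samples

    @property
    def n_taxa(self) -> int:
        return self.taxa.n_taxa

    def subset_samples(self, idx: np.ndarray) -> "StudyData":
        idx = np.asarray(idx)
        ids = [self.taxa.sample_ids[i] for i in idx]
        taxa = TaxaTable(ids, self.taxa.taxon_ids, self.taxa.values[idx])
        meta = SampleMetadata(
            self.meta.frame.iloc[idx],
            self.meta.exposure,
            self.meta.outcome,
            self.meta.covariates,
        )
        return StudyData(taxa, meta)


def _normalize_rows(values: np.ndarray, ids: Sequence) -> np.ndarray:
    sums = values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = [ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sample rows: {bad}")
    # leave rows that are already on the simplex untouched so that
    # write -> read round-trips are bit-identical
    needs = np.abs(sums - 1.0) > 1e-9
    out = values.copy()
    out[needs] = values[needs] / sums[needs, None]
    return out


def _read_biom(path) -> pd.DataFrame:
    """Minimal BIOM 2.1 (HDF5) reader returning an observations x samples frame."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        obs_ids = [s.decode() if isinstance(s, bytes) else s for s in fh["observation/ids"][:]]
        samp_ids = [s.decode() if isinstance(s, bytes) else s for s in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(samp_ids)),
        )
    return pd.DataFrame(mat.toarray(), index=obs_ids, columns=samp_ids)


def read_taxa_table(path, format=None, orientation="auto", normalize=True) -> TaxaTable:
    """Read a taxa abundance table from TSV/CSV (or BIOM 2.1 HDF5).

    Counts or abundances are row-normalized to relative abundances.
    Orientation (samples-as-rows vs taxa-as-rows) is auto-detected by
    which axis has row sums nearer 1 after normalization; pass
    ``orientation='samples'`` or ``'taxa'`` to override (meaning which
    entity the file's *rows* are).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".csv": "csv", ".biom": "biom"}.get(suffix, "tsv")
    if format == "biom":
        frame = _read_biom(path).T  # samples as rows
        orientation = "samples"
    else:
        sep = "," if format == "csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    values = frame.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"negative values in {path}")

    if orientation == "auto":
        # score each layout by closeness of raw sums to the simplex
        def score(v):
            s = v.sum(axis=1)
            s = s[s > 0]
            return np.abs(s - 1.0).mean() if s.size else np.inf

        orientation = "samples" if score(values) <= score(values.T) else "taxa"
    if orientation == "taxa":
        frame = frame.T
        values = values.T
    sample_ids = [str(i) for i in frame.index]
    taxon_ids = [str(c) for c in frame.columns]
    if normalize:
        values = _normalize_rows(values, sample_ids)
    return TaxaTable(sample_ids, taxon_ids, values)


def write_taxa_table(table: TaxaTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(
    path,
    exposure: str,
    outcome: str,
    covariates: Sequence[str] = (),
    reference_label=None,
) -> SampleMetadata:
    """Read sample metadata from TSV/CSV.

    If ``reference_label`` is given, the exposure column is recoded to 1
    where it equals that label and 0 elsewhere (after checking the
    column is binary); otherwise it must already be 0/1.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    frame.index = frame.index.map(str)
    if reference_label is not None:
        col = frame[exposure]
        levels = set(col.astype(str).unique())
        if str(reference_label) not in levels:
            raise ValueError(
                f"reference label {reference_label!r} not found in "
                f"exposure column (levels: {sorted(levels)})"
            )
        if len(levels) != 2:
            raise ValueError(f"exposure must be binary, got levels {sorted(levels)}")
        frame = frame.assign(**{exposure: (col.astype(str) == str(reference_label)).astype(int)})
    return SampleMetadata(frame, exposure, outcome, covariates)


def assemble_study(taxa: TaxaTable, meta: SampleMetadata) -> StudyData:
    """Inner-join taxa table and metadata on sample ids.

    Sample order of the taxa table is preserved; the count of samples
    present in only one input is recorded on ``StudyData.n_dropped``.
    """
    shared = [s for s in taxa.sample_ids if s in set(meta.sample_ids)]
    if not shared:
        raise ValueError("no overlapping sample ids between taxa table and metadata")
    n_dropped = (len(taxa.sample_ids) - len(shared)) + (len(meta.sample_ids) - len(shared))
    idx = [taxa.sample_ids.index(s) for s in shared]
    sub_taxa = TaxaTable(shared, taxa.taxon_ids, taxa.values[idx])
    sub_meta = SampleMetadata(
        meta.frame.loc[shared], meta.exposure, meta.outcome, meta.covariates
    )
    out = StudyData(sub_taxa, sub_meta)
    out.n_dropped = n_dropped
    return out


def write_results(result, path) -> dict:
    """Write a disparity analysis result to ``<path>.tsv`` + ``<path>.json``.

    ``result`` is a :class:`micromediate.inference.DisparityReport`.
    Returns the JSON-serializable summary dict.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    per_taxon = result.per_taxon_frame()
    per_taxon.to_csv(path.with_suffix(".tsv"), sep="\t", index_label="taxon_id")
    summary = result.summary_dict()
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
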