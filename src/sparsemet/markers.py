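"""Marker quality control, mean imputation, and genomic relationship matrices.

Markers are biallelic SNPs in additive coding: 0 = homozygous minor,
1 = heterozygous, 2 = homozygous major; missing entries are NaN.  The
genomic relationship matrix (GRM) is ``G = XX'/p`` where ``X`` is the
column-centered, column-standardized marker matrix and ``p`` the number
of markers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "GRM",
    "QCReport",
    "qc_filter",
    "impute_mean",
    "grm",
    "read_marker_csv",
    "write_marker_csv",
    "read_plink_raw",
    "write_plink_raw",
    "read_grm_csv",
    "write_grm_csv",
]

#: removal reasons qc_filter may assign (plus "kept")
QC_REASONS = ("no_calls", "max_missing", "min_callrate", "min_maf", "max_het")


@dataclass
class MarkerMatrix:
    """Genotypes x markers grid with entries in {0, 1, 2, NaN}.

    After mean imputation entries are real-valued.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_g, n_m = self.values.shape
        if len(self.genotype_ids) != n_g or len(self.marker_ids) != n_m:
            raise ValueError("ID lists do not match the value grid dimensions")
        if len(set(self.genotype_ids)) != n_g:
            raise ValueError("duplicate genotype IDs")
        if len(set(self.marker_ids)) != n_m:
            raise ValueError("duplicate marker IDs")

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genotype_ids, columns=self.marker_ids
        )


@dataclass
class GRM:
    """Symmetric genomic relationship matrix over a set of genotypes."""

    genotype_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genotype_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square and match the ID list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        tr = float(np.trace(self.values))
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8 * max(tr, 1.0):
            raise ValueError(f"GRM is not PSD (min eigenvalue {w.min():.3e})")
        self._index = {g: i for i, g in enumerate(self.genotype_ids)}

    def subset(self, genotype_ids: list[str]) -> "GRM":
        idx = [self._index[g] for g in genotype_ids]
        return GRM(list(genotype_ids), self.values[np.ix_(idx, idx)])


@dataclass
class QCReport:
    """Per-marker QC statistics and the filtering decision for each."""

    table: pd.DataFrame = field(repr=False)

    @property
    def n_kept(self) -> int:
        return int((self.table["decision"] == "kept").sum())

    @property
    def n_removed(self) -> int:
        return len(self.table) - self.n_kept


def _marker_stats(values: np.ndarray) -> pd.DataFrame:
    """MAF, missing fraction, call rate and heterozygosity per marker.

    All statistics use non-missing calls only: imputation would bias the
    allele frequencies toward the column mean.
    """
    n_g = values.shape[0]
    missing = np.isnan(values)
    n_called = (~missing).sum(axis=0)
    call_rate = n_called / n_g
    with np.errstate(invalid="ignore"):
        mean_call = np.nansum(values, axis=0) / np.where(n_called > 0, n_called, 1)
        freq = mean_call / 2.0  # frequency of the allele counted by the coding
        maf = np.minimum(freq, 1.0 - freq)
        het = np.nansum(values == 1, axis=0) / np.where(n_called > 0, n_called, 1)
    maf = np.where(n_called > 0, maf, np.nan)
    het = np.where(n_called > 0, het, np.nan)
    return pd.DataFrame(
        {
            "maf": maf,
            "missing_frac": 1.0 - call_rate,
            "call_rate": call_rate,
            "het_frac": het,
            "n_called": n_called,
        }
    )


def qc_filter(
    markers: MarkerMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
    min_callrate: float = 0.80,
    max_het: float = 0.95,
) -> tuple[MarkerMatrix, QCReport]:
    """Remove markers failing any quality filter.

    A marker is removed iff (strict inequalities, boundaries kept):

    * missing fraction  > ``max_missing``
    * minor allele freq < ``min_maf``
    * call rate         < ``min_callrate``
    * heterozygosity    > ``max_het``

    A marker with zero non-missing calls is removed with reason
    ``no_calls``.  Multiple violated filters are all reported,
    semicolon-joined (missing fraction and call rate are complementary
    statistics, so ``max_missing``/``min_callrate`` often co-occur).

    Returns the filtered matrix and a :class:`QCReport` recording every
    decision.  Idempotent: filtering an already-filtered matrix removes
    nothing.
    """
    if not (0 <= max_missing < 1 and 0 < min_maf <= 0.5):
        raise ValueError("invalid QC thresholds")
    stats = _marker_stats(markers.values)
    reasons: list[str] = []
    for _, row in stats.iterrows():
        if row["n_called"] == 0:
            reasons.append("no_calls")
            continue
        why = []
        if row["missing_frac"] > max_missing:
            why.append("max_missing")
        if row["call_rate"] < min_callrate:
            why.append("min_callrate")
        if row["maf"] < min_maf:
            why.append("min_maf")
        if row["het_frac"] > max_het:
            why.append("max_het")
        reasons.append(";".join(why) if why else "kept")
    stats = stats.drop(columns="n_called")
    stats.insert(0, "marker_id", markers.marker_ids)
    stats["decision"] = reasons
    keep = [i for i, r in enumerate(reasons) if r == "kept"]
    filtered = MarkerMatrix(
        list(markers.genotype_ids),
        [markers.marker_ids[i] for i in keep],
        markers.values[:, keep].copy(),
    )
    return filtered, QCReport(stats.reset_index(drop=True))


def impute_mean(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing entry by its marker's mean over non-missing calls."""
    values = markers.values.copy()
    missing = np.isnan(values)
    n_called = (~missing).sum(axis=0)
    if (n_called == 0).any():
        bad = [markers.marker_ids[i] for i in np.where(n_called == 0)[0]]
        raise ValueError(
            f"markers with no calls cannot be mean-imputed (run qc_filter first): {bad}"
        )
    col_means = np.nansum(values, axis=0) / n_called
    values[missing] = np.broadcast_to(col_means, values.shape)[missing]
    return MarkerMatrix(list(markers.genotype_ids), list(markers.marker_ids), values)


def grm(markers: MarkerMatrix) -> GRM:
    """Genomic relationship matrix G = XX'/p from standardized markers.

    Columns are centered to mean zero and scaled to unit sample variance
    (n-1 denominator); p is the number of markers.  The input must be
    complete (impute first) and every column must vary.
    """
    values = markers.values
    if np.isnan(values).any():
        raise ValueError("marker matrix has missing entries; impute first")
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [markers.marker_ids[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance marker columns cannot be standardized: {bad}")
    x = (values - values.mean(axis=0)) / sd
    g = x @ x.T / markers.n_markers
    g = (g + g.T) / 2.0  # enforce exact symmetry against rounding
    return GRM(list(markers.genotype_ids), g)


# ---------------------------------------------------------------------------
# I/O: CSV (rows = genotypes, header = marker IDs, NA = missing) and
# PLINK-.raw-style whitespace text.
# ---------------------------------------------------------------------------

def read_marker_csv(path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    return MarkerMatrix(
        [str(g) for g in df.index], [str(m) for m in df.columns], df.to_numpy(float)
    )


def write_marker_csv(markers: MarkerMatrix, path) -> None:
    markers.to_frame().to_csv(path, index_label="genotype", na_rep="NA")


_RAW_META = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}


def read_plink_raw(path) -> MarkerMatrix:
    """Read PLINK --recode A style whitespace text.

    Header metadata columns (FID/IID/PAT/MAT/SEX/PHENOTYPE) are tolerated;
    IID (or FID if IID is absent) supplies the genotype ID and the rest are
    ignored.  NA encodes missing.
    """
    df = pd.read_csv(path, sep=r"\s+")
    id_col = "IID" if "IID" in df.columns else "FID" if "FID" in df.columns else None
    marker_cols = [c for c in df.columns if c.upper() not in _RAW_META]
    if id_col is None:
        ids = [str(i) for i in df.index]
    else:
        ids = [str(v) for v in df[id_col]]
    return MarkerMatrix(ids, marker_cols, df[marker_cols].to_numpy(float))


def write_plink_raw(markers: MarkerMatrix, path) -> None:
    df = markers.to_frame()
    out = pd.DataFrame({"FID": markers.genotype_ids, "IID": markers.genotype_ids})
    out = pd.concat([out.reset_index(drop=True), df.reset_index(drop=True)], axis=1)
    buf = io.StringIO()
    out.to_csv(buf, sep=" ", index=False, na_rep="NA")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_grm_csv(path) -> GRM:
    df = pd.read_csv(path, index_col=0)
    return GRM([str(g) for g in df.index], df.to_numpy(float))


def write_grm_csv(g: GRM, path) -> None:
    pd.DataFrame(g.values, index=g.genotype_ids, columns=g.genotype_ids).to_csv(
        path, index_label="genotype"
    )
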