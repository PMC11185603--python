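"""Cancer expression input and per-gene summary features.

The user-supplied tumor expression matrix (genes x samples, proteomic
intensities or RNA TPM/RPKM) is summarized into five per-gene features that
form the first columns of the genes-by-features scoring matrix:

* ``mean_expr`` / ``max_expr`` — mean / maximum over non-missing samples;
* ``n_expressed`` — number of samples with any expression (value > 0);
* ``n_high`` — samples strictly above a dataset-global high threshold
  (default: the 80th percentile of all values in the matrix);
* ``n_low`` — samples strictly below a dataset-global low threshold
  (default: the 20th percentile).

Thresholds are global percentiles of the whole matrix, not per gene: "low"
and "high" are meant relative to what the dataset as a whole measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import log, normalize_gene, percentile

SUMMARY_FEATURES = ("mean_expr", "max_expr", "n_expressed", "n_high", "n_low")


@dataclass
class ExpressionDataset:
    """Genes x samples non-negative expression matrix with a phenotype label.

    ``values`` is a DataFrame indexed by normalized, unique gene symbols with
    one column per sample; missing measurements are NaN.
    """

    values: pd.DataFrame
    phenotype: str = ""
    unit: str = "intensity"

    def __post_init__(self) -> None:
        idx = pd.Index([normalize_gene(g) for g in self.values.index], name="gene")
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after normalization: {dups[:5]}")
        self.values = self.values.set_axis(idx, axis=0)
        arr = self.values.to_numpy(dtype=float)
        if arr.size == 0:
            raise ValueError("empty expression matrix")
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionSummary:
    """Five summary features per gene plus the global thresholds used."""

    features: pd.DataFrame  # genes x SUMMARY_FEATURES
    theta_low: float
    theta_high: float
    provenance: dict = field(default_factory=dict)


def load_expression(path, fmt: str | None = None, phenotype: str = "",
                    unit: str = "intensity") -> ExpressionDataset:
    """Read a TSV/CSV expression table into an :class:`ExpressionDataset`.

    Column 1 holds gene symbols; remaining columns are numeric sample values
    (blank or ``NA`` cells become missing). Duplicate gene rows are collapsed
    by the per-sample maximum, keeping the strongest detection evidence.
    """
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.lower().endswith(".csv") else "tsv"
    sep = "," if fmt == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, header=0, na_values=["NA", ""], dtype={0: str})
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise ValueError(f"unreadable expression file {path!r}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(
            f"no numeric columns in {path!r}: found {df.shape[1]} column(s), "
            "need gene symbol + at least one sample"
        )
    if df.shape[0] == 0:
        raise ValueError(f"empty expression matrix in {path!r}: 0 data rows")
    gene_col = df.columns[0]
    df[gene_col] = df[gene_col].map(normalize_gene)
    for col in df.columns[1:]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    collapsed = df.groupby(gene_col, sort=True).max()
    n_dup = df.shape[0] - collapsed.shape[0]
    if n_dup:
        log.info("collapsed %d duplicate gene rows by per-sample maximum", n_dup)
    return ExpressionDataset(values=collapsed, phenotype=phenotype, unit=unit)


def summarize_expression(ds: ExpressionDataset, low_pct: float = 20.0,
                         high_pct: float = 80.0) -> ExpressionSummary:
    """Compute the five per-gene summary features.

    ``low_pct``/``high_pct`` are the dataset-global percentile cut-offs for the
    "low"/"high" expression counts; comparisons against the thresholds are
    strict, so ties at a threshold are not counted.
    """
    if not 0 <= low_pct <= high_pct <= 100:
        raise ValueError(f"need 0 <= low_pct <= high_pct <= 100, got {low_pct}, {high_pct}")
    arr = ds.values.to_numpy(dtype=float)
    if np.all(np.isnan(arr)):
        raise ValueError("all-missing expression matrix")
    theta_low = percentile(arr.ravel(), low_pct)
    theta_high = percentile(arr.ravel(), high_pct)
    with np.errstate(invalid="ignore"):
        feats = pd.DataFrame(
            {
                "mean_expr": np.nanmean(arr, axis=1),
                "max_expr": np.nanmax(np.where(np.isnan(arr), -np.inf, arr), axis=1),
                "n_expressed": np.nansum(arr > 0, axis=1).astype(float),
                "n_high": np.nansum(arr > theta_high, axis=1).astype(float),
                "n_low": np.nansum(arr < theta_low, axis=1).astype(float),
            },
            index=ds.values.index,
        )
    # genes with no observed value at all keep NaN summaries
    all_nan = np.all(np.isnan(arr), axis=1)
    feats.loc[all_nan, :] = np.nan
    feats.loc[feats["max_expr"] == -np.inf, "max_expr"] = np.nan
    return ExpressionSummary(
        features=feats,
        theta_low=theta_low,
        theta_high=theta_high,
        provenance={"low_pct": low_pct, "high_pct": high_pct, "unit": ds.unit},
    )
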