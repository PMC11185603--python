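"""Shared helpers: symbol normalization, percentiles, logging."""

from __future__ import annotations

import logging
import sys

import numpy as np

log = logging.getLogger("immunorank")


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else (logging.ERROR if quiet else logging.INFO)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


def normalize_gene(symbol: str) -> str:
    """Canonical gene symbol: uppercased, surrounding whitespace stripped."""
    return str(symbol).strip().upper()


def normalize_label(text: str) -> str:
    """Canonical free-text key (disease, phenotype): lowercased, trimmed."""
    return str(text).strip().lower()


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile over non-missing values.

    The single percentile rule used throughout the package (thresholds on
    expression, normal-tissue restriction) so every cut-off is reproducible.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("percentile of an all-missing array")
    return float(np.percentile(arr, q, method="linear"))
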