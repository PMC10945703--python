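"""Depth filtering, transcripts-per-50,000 scaling and per-embryo
standardization.

The normalization chain mirrors a whole-embryo collection design: cells
below a mapped-read depth threshold are discarded, UMI counts are scaled
to a fixed per-cell total of 50,000 transcripts, log10-transformed with a
pseudocount, and finally each gene is z-scored *within each embryo* so
that embryo-level batch signatures (library efficiency, staging jitter,
maternal load) cancel and cells are comparable between embryos.

Layers written on the AnnData: ``tp50k``, ``log10``, ``z``. The raw
counts stay in ``X``.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np

TP50K_TOTAL = 50_000.0


def filter_cells(adata: ad.AnnData, min_reads: int = 10_000) -> ad.AnnData:
    """Keep cells with *strictly more* than ``min_reads`` mapped reads.

    Cell order is preserved. An empty result warns rather than raises so
    a pipeline over many stages can report the offending stage itself.
    """
    if "mapped_reads" not in adata.obs:
        raise ValueError("obs lacks a 'mapped_reads' column")
    keep = adata.obs["mapped_reads"].to_numpy() > min_reads
    if not keep.any():
        warnings.warn(
            f"no cells exceed {min_reads} mapped reads; returning an empty matrix",
            stacklevel=2,
        )
    return adata[keep].copy()


def normalize_tp50k(adata: ad.AnnData) -> ad.AnnData:
    """Scale each cell to 50,000 transcripts (layer ``tp50k``)."""
    X = np.asarray(adata.X, dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad}")
    adata.layers["tp50k"] = X / totals[:, None] * TP50K_TOTAL
    return adata


def log_transform(adata: ad.AnnData, pseudocount: float = 1.0) -> ad.AnnData:
    """log10(tp50k + pseudocount) into layer ``log10``."""
    if "tp50k" not in adata.layers:
        normalize_tp50k(adata)
    adata.layers["log10"] = np.log10(adata.layers["tp50k"] + pseudocount)
    adata.uns["pseudocount"] = pseudocount
    return adata


def standardize_within_embryo(
    adata: ad.AnnData,
    layer: str = "log10",
    sd: str = "population",
    pseudocount: float = 1.0,
) -> ad.AnnData:
    """z-score each gene across the cells of each embryo (layer ``z``).

    Standardization acts on the log10 layer (created on demand with the
    given pseudocount). Per gene and embryo the mean becomes 0 and the sd
    1; genes with zero variance within an embryo are set to 0 rather than
    dropped so matrices stay aligned across embryos.

    ``sd`` selects the divisor: ``"population"`` (divide by n, so two
    cells map to ±1) or ``"sample"`` (divide by n−1).
    """
    if sd not in ("population", "sample"):
        raise ValueError("sd must be 'population' or 'sample'")
    if "embryo_id" not in adata.obs:
        raise ValueError("obs lacks an 'embryo_id' column")
    if layer not in adata.layers:
        if layer == "log10":
            log_transform(adata, pseudocount)
        else:
            raise ValueError(f"layer {layer!r} not present")
    X = np.asarray(adata.layers[layer], dtype=float)
    Z = np.empty_like(X)
    ddof = 0 if sd == "population" else 1
    embryos = adata.obs["embryo_id"].to_numpy()
    for embryo in np.unique(embryos):
        rows = np.flatnonzero(embryos == embryo)
        if len(rows) < 2:
            raise ValueError(
                f"embryo {embryo!r} has a single cell; the within-embryo "
                "standard deviation is undefined"
            )
        block = X[rows]
        mu = block.mean(axis=0)
        sigma = block.std(axis=0, ddof=ddof)
        with np.errstate(invalid="ignore", divide="ignore"):
            zb = (block - mu) / sigma
        zb[:, sigma == 0] = 0.0
        Z[rows] = zb
    adata.layers["z"] = Z
    return adata


def preprocess(
    adata: ad.AnnData,
    min_reads: int = 10_000,
    pseudocount: float = 1.0,
    sd: str = "population",
) -> ad.AnnData:
    """Full chain: depth filter -> tp50k -> log10 -> per-embryo z."""
    adata = filter_cells(adata, min_reads)
    normalize_tp50k(adata)
    log_transform(adata, pseudocount)
    standardize_within_embryo(adata, sd=sd, pseudocount=pseudocount)
    return adata
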