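"""Single-cell expression prevalence in the Grpr population.

The pipeline mirrors the study's processing of the Häring et al. spinal
dorsal-horn dataset: per-cell normalization to the median depth, log1p,
selection of *Grpr*-expressing cells (normalized expression > 0.01), and
per-gene prevalence — the percentage of selected cells in which a gene's
normalized expression exceeds the threshold.  Normalization and the log
transform are delegated to scanpy, the same toolkit the original analysis
used.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .trace import ParameterError

#: Marker genes (excitatory/inhibitory identity) profiled in the study.
MARKER_PANEL = ["Slc17a6", "Slc32a1", "Pax2", "Tlx3", "Ebf2"]
#: Receptor-subunit panels: AMPA, GABA-A and glycine receptor subunits.
SUBUNIT_PANEL = (
    [f"Gria{i}" for i in range(1, 5)]
    + [f"Gabra{i}" for i in range(1, 7)]
    + [f"Glra{i}" for i in range(1, 5)]
    + ["Glrb"]
)
DEFAULT_PANEL = MARKER_PANEL + SUBUNIT_PANEL

#: Expression threshold in normalized (post-log1p) units.
DEFAULT_THRESHOLD = 0.01


@dataclass
class CountMatrix:
    """Genes × cells counts with label vectors and processing flags."""

    counts: sp.spmatrix
    gene_labels: list[str]
    cell_labels: list[str]
    normalized: bool = False
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_labels), len(self.cell_labels)):
            raise ParameterError(
                "label lengths must match the matrix dimensions"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ParameterError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        """Index of ``gene``; exact match preferred, else case-insensitive."""
        try:
            return self.gene_labels.index(gene)
        except ValueError:
            lowered = [g.lower() for g in self.gene_labels]
            try:
                return lowered.index(gene.lower())
            except ValueError:
                raise KeyError(f"gene {gene!r} not present") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()


def normalize_and_log(m: CountMatrix) -> CountMatrix:
    """Scale each cell to the median depth, then apply log(1+x).

    Cells with zero total counts are dropped with a warning.  Raises on an
    all-zero matrix or on already-processed input.
    """
    import scanpy as sc
    from anndata import AnnData

    if m.normalized or m.log_transformed:
        raise ParameterError("matrix is already normalized/log-transformed")
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if totals.sum() == 0:
        raise ParameterError("all-zero count matrix")
    keep = totals > 0
    cell_labels = list(m.cell_labels)
    counts = m.counts
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero cells before normalization",
            stacklevel=2,
        )
        counts = counts[:, keep]
        cell_labels = [c for c, k in zip(cell_labels, keep) if k]

    # scanpy works on cells × genes; normalize_total with target_sum=None
    # scales every cell to the median of the pre-normalization totals.
    adata = AnnData(
        X=sp.csr_matrix(counts.T),
        obs=pd.DataFrame(index=cell_labels),
        var=pd.DataFrame(index=m.gene_labels),
    )
    sc.pp.normalize_total(adata, target_sum=None)
    sc.pp.log1p(adata)
    return CountMatrix(
        counts=sp.csr_matrix(adata.X.T),
        gene_labels=list(m.gene_labels),
        cell_labels=cell_labels,
        normalized=True,
        log_transformed=True,
    )


def select_population(
    m: CountMatrix,
    gene: str = "Grpr",
    threshold: float = DEFAULT_THRESHOLD,
    direction: str = "greater",
) -> CountMatrix:
    """Cells in which ``gene`` is expressed (normalized expression > threshold).

    ``direction="less"`` selects the complement-side rule instead; the
    strict ``>`` rule is the default.  An empty selection is returned (and
    flagged with a warning) rather than raising.
    """
    if not (m.normalized and m.log_transformed):
        raise ParameterError("select_population requires a normalized, logged matrix")
    vals = m.gene_values(gene)
    if direction == "greater":
        mask = vals > threshold
    elif direction == "less":
        mask = vals < threshold
    else:
        raise ParameterError("direction must be 'greater' or 'less'")
    if not mask.any():
        warnings.warn(f"no cells selected for {gene!r}", stacklevel=2)
    return replace(
        m,
        counts=m.counts[:, mask],
        gene_labels=list(m.gene_labels),
        cell_labels=[c for c, k in zip(m.cell_labels, mask) if k],
    )


@dataclass
class PrevalencePanel:
    """Per-gene expression prevalence within a selected population."""

    prevalence_pct: dict[str, float]
    threshold: float
    population_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.prevalence_pct),
                "prevalence_pct": list(self.prevalence_pct.values()),
            }
        )


def gene_prevalence(
    m: CountMatrix,
    panel: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> PrevalencePanel:
    """Percentage of cells expressing each panel gene above threshold."""
    if panel is None:
        panel = DEFAULT_PANEL
    if not panel:
        raise ParameterError("panel must contain at least one gene")
    if m.n_cells == 0:
        raise ParameterError("selected population is empty")
    prevalence = {
        gene: float(100.0 * np.mean(m.gene_values(gene) > threshold))
        for gene in panel
    }
    return PrevalencePanel(
        prevalence_pct=prevalence,
        threshold=threshold,
        population_size=m.n_cells,
    )
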