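"""Sparse gene×cell count matrices with planted per-gene prevalence."""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..trace import ParameterError
from .params import GroundTruth
from ..scrna import CountMatrix


def gen_count_matrix(
    n_genes: int,
    n_cells: int,
    planted_prevalence: dict[str, float] | np.ndarray | float = 0.1,
    depth_dist: tuple[float, float] = (1.0, 0.3),
    mean_count: float = 3.0,
    seed: int | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Draw counts so each gene is nonzero in ≈ its planted cell fraction.

    ``planted_prevalence`` may be a scalar (all genes), a per-gene array,
    or a ``{gene_name: fraction}`` dict for named genes (remaining genes
    get a background prevalence drawn uniformly from [0.02, 0.3]).  Per-cell
    sequencing depth factors are lognormal with the given (mean, sd of log).
    Nonzero entries are ``1 + Poisson(depth·(mean_count − 1))`` so that an
    expressed gene always stays nonzero and survives median-depth
    normalization well above the expression threshold.
    """
    rng = np.random.default_rng(seed)
    gene_labels = [f"gene{i:05d}" for i in range(n_genes)]

    if isinstance(planted_prevalence, dict):
        prevalence = rng.uniform(0.02, 0.3, size=n_genes)
        for j, (name, p) in enumerate(planted_prevalence.items()):
            if j >= n_genes:
                raise ParameterError("more named genes than n_genes")
            gene_labels[j] = name
            prevalence[j] = p
    else:
        prevalence = np.broadcast_to(
            np.asarray(planted_prevalence, dtype=float), (n_genes,)
        ).copy()
    if np.any((prevalence < 0) | (prevalence > 1)):
        raise ParameterError("planted prevalence must lie in [0, 1]")

    depth = rng.lognormal(mean=np.log(depth_dist[0]), sigma=depth_dist[1], size=n_cells)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for g in range(n_genes):
        k = rng.binomial(n_cells, prevalence[g])
        if k == 0:
            continue
        cells = rng.choice(n_cells, size=k, replace=False)
        counts = 1 + rng.poisson(depth[cells] * max(mean_count - 1.0, 0.0))
        rows.append(np.full(k, g))
        cols.append(cells)
        vals.append(counts)

    if rows:
        mat = sp.coo_matrix(
            (
                np.concatenate(vals).astype(float),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(n_genes, n_cells),
        ).tocsr()
    else:
        mat = sp.csr_matrix((n_genes, n_cells))

    cm = CountMatrix(
        counts=mat,
        gene_labels=gene_labels,
        cell_labels=[f"cell{i:05d}" for i in range(n_cells)],
    )
    truth = GroundTruth(
        planted_prevalence={g: float(p) for g, p in zip(gene_labels, prevalence)},
        extra={"depth_factors": depth},
    )
    return cm, truth
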