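"""Synthetic count matrices with planted gene-correlation blocks.

The generator mirrors the statistical structure the analysis assumes:
negative-binomial counts with log-normal gene base expression, log-normal
cell size factors, a shared dispersion ``theta_true``, and latent Gaussian
factors that induce block correlation among genes.

Generative chain, for cell ``c`` and gene ``g``:

* per-cell global factor ``G_c ~ N(0,1)`` and per-block factors
  ``F_bc = sqrt(alpha) G_c + sqrt(1-alpha) H_bc`` with
  ``alpha = rho_between / rho_within`` (so latent correlation is
  ``rho_within`` within a block and ``rho_between`` across blocks);
* latent ``z_cg = sqrt(rho_within) F_b(g),c + sqrt(1-rho_within) eps_cg``
  for block genes, iid ``N(0,1)`` for unstructured genes;
* rate ``mu_cg = s_c * m_g * exp(coupling_sd * z_cg - coupling_sd**2 / 2)``
  (the −σ²/2 offset keeps ``E[exp(.)] = 1`` so ``m_g`` is the gene mean);
* ``X_cg ~ NB(mean mu_cg, dispersion theta_true)``.

Latent correlation is attenuated by the exponential link and NB sampling;
the observed residual correlation is measured by the tests, not assumed.

Defaults emulate a reliably expressed droplet-data gene panel (the regime
left after intersecting detection filters across time points): log-normal
gene means with median ~4 counts/cell and log-sd 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .containers import CountMatrix

__all__ = ["SyntheticSpec", "generate_block_counts", "generate_null_counts"]

LOG_MEDIAN_COUNT = float(np.log(4.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the block-correlated NB count generator."""

    n_cells: int = 1000
    n_genes: int = 400
    block_sizes: tuple[int, ...] = (50, 50)
    rho_within: float = 0.8
    rho_between: float = 0.0
    gene_mean_log_mu: float = LOG_MEDIAN_COUNT
    gene_mean_log_sd: float = 0.7
    cell_size_log_sd: float = 0.3
    theta_true: float = 50.0
    coupling_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if sum(self.block_sizes) > self.n_genes:
            raise ValueError("block sizes sum exceeds n_genes")
        if not 0 <= self.rho_within < 1:
            raise ValueError("rho_within must lie in [0, 1)")
        if self.rho_between < 0 or self.rho_between > self.rho_within:
            raise ValueError("rho_between must lie in [0, rho_within]")
        if self.theta_true <= 0:
            raise ValueError("theta_true must be positive")
        if self.coupling_sd < 0:
            raise ValueError("coupling_sd must be non-negative")


def generate_block_counts(spec: SyntheticSpec) -> tuple[CountMatrix, list[int]]:
    """Draw a count matrix with planted blocks; returns (counts, labels).

    ``labels[g]`` is the 0-based block index of gene ``g`` or −1 for
    unstructured genes. Genes 0..sum(block_sizes)−1 are the block genes, in
    block order.
    """
    rng = np.random.default_rng(spec.seed)
    n_c, n_g = spec.n_cells, spec.n_genes
    labels = np.full(n_g, -1, dtype=int)
    start = 0
    for b, size in enumerate(spec.block_sizes):
        labels[start : start + size] = b
        start += size

    m_g = rng.lognormal(spec.gene_mean_log_mu, spec.gene_mean_log_sd, n_g)
    s_c = rng.lognormal(-spec.cell_size_log_sd**2 / 2, spec.cell_size_log_sd, n_c)

    global_f = rng.standard_normal(n_c)
    block_h = rng.standard_normal((len(spec.block_sizes), n_c))
    if spec.rho_within > 0 and spec.rho_between > 0:
        alpha = spec.rho_between / spec.rho_within
        block_f = np.sqrt(alpha) * global_f + np.sqrt(1 - alpha) * block_h
    else:
        block_f = block_h
    eps = rng.standard_normal((n_c, n_g))

    z = eps.copy()
    block_genes = labels >= 0
    if block_genes.any() and spec.rho_within > 0:
        z[:, block_genes] = (
            np.sqrt(spec.rho_within) * block_f[labels[block_genes]].T
            + np.sqrt(1 - spec.rho_within) * eps[:, block_genes]
        )

    cs = spec.coupling_sd
    mu = s_c[:, None] * m_g[None, :] * np.exp(cs * z - cs**2 / 2)
    theta = spec.theta_true
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    cm = CountMatrix(
        counts,
        [f"cell{i:05d}" for i in range(n_c)],
        [f"gene{j:05d}" for j in range(n_g)],
    )
    return cm, labels.tolist()


def generate_null_counts(spec: SyntheticSpec) -> CountMatrix:
    """Same marginal model with ``coupling_sd = 0``: no latent correlation."""
    cm, _ = generate_block_counts(replace(spec, coupling_sd=0.0))
    return cm
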