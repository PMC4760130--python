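"""Synthetic expression matrices with planted modules and known ground truth.

The generator instantiates exactly the model the scorer inverts: each planted
gene's expression is a linear response to one or more hidden factors,
``X[g, s] = sum_k alpha_k[g] * A_k[s] + noise``, embedded in a background of
iid Gaussian genes.  A single planted factor yields a coordinated,
overdispersed module; two or more independent factors yield an overdispersed
but *uncoordinated* module (no dominant spectral gap).  Everything is
seed-reproducible, and the true loadings/activities are returned so recovery
can be measured directly.

Noise is Gaussian; signal-to-noise is quoted as per-gene signal standard
deviation over the noise standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import ExpressionMatrix, ModuleDefinition, ModuleGene
from .exceptions import RomaError
from .preprocess import center_rows


@dataclass
class PlantedModuleSpec:
    """Specification of one planted module.

    ``true_loadings`` has shape (n_factors, n_genes), each row unit Euclidean
    norm; ``true_activity`` has shape (n_factors, n_samples).  One factor is
    the coordinated case; two or more independent factors give an
    overdispersed-but-uncoordinated module.
    """

    name: str
    true_loadings: np.ndarray
    true_activity: np.ndarray
    noise_sd: float = 0.0
    signed_fraction: float = 0.5   #: fraction of genes given signed GMT weights

    def __post_init__(self) -> None:
        self.true_loadings = np.atleast_2d(np.asarray(self.true_loadings, dtype=float))
        self.true_activity = np.atleast_2d(np.asarray(self.true_activity, dtype=float))
        if self.true_loadings.shape[0] != self.true_activity.shape[0]:
            raise ValueError("loadings and activity disagree on the number of factors")
        if self.n_genes < 2:
            raise ValueError("a planted module needs >= 2 genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        norms = np.linalg.norm(self.true_loadings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("every factor's loading vector must have unit norm")

    @property
    def n_factors(self) -> int:
        return self.true_loadings.shape[0]

    @property
    def n_genes(self) -> int:
        return self.true_loadings.shape[1]

    @property
    def n_samples(self) -> int:
        return self.true_activity.shape[1]


def single_factor_spec(
    name: str,
    n_genes: int,
    n_samples: int,
    snr: float,
    noise_sd: float = 1.0,
    rng: np.random.Generator | int | None = 0,
    n_factors: int = 1,
) -> PlantedModuleSpec:
    """Convenience constructor for planted factor specs at a target SNR.

    Loadings are ``+-1/sqrt(n_genes)`` with random signs (for multiple
    factors, genes are split into equal blocks, one factor per block, with
    within-block loadings renormalised); activities are Gaussian with
    standard deviation chosen so that each planted gene's signal standard
    deviation is ``snr * noise_sd``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_factors < 1 or n_factors > n_genes // 2:
        raise ValueError("n_factors must be >= 1 and leave >= 2 genes per factor")
    loadings = np.zeros((n_factors, n_genes))
    bounds = np.linspace(0, n_genes, n_factors + 1).astype(int)
    for k in range(n_factors):
        lo, hi = bounds[k], bounds[k + 1]
        block = rng.choice([-1.0, 1.0], size=hi - lo) / np.sqrt(hi - lo)
        loadings[k, lo:hi] = block
    # per-gene |alpha| = 1/sqrt(block); sd(A) = snr * noise_sd * sqrt(block)
    activity = np.empty((n_factors, n_samples))
    for k in range(n_factors):
        block_size = bounds[k + 1] - bounds[k]
        activity[k] = rng.standard_normal(n_samples) * snr * noise_sd * np.sqrt(block_size)
    return PlantedModuleSpec(name, loadings, activity, noise_sd=noise_sd)


def generate(
    n_background_genes: int,
    n_samples: int,
    specs: Sequence[PlantedModuleSpec],
    background_sd: float = 1.0,
    seed: int = 0,
    n_control_modules: int = 0,
    control_size: int | None = None,
) -> tuple[ExpressionMatrix, dict[str, dict[str, np.ndarray]], list[ModuleDefinition]]:
    """Assemble a full expression matrix with planted modules.

    Background genes are iid Gaussian(0, background_sd^2).  Planted genes
    follow their spec's factor model plus Gaussian(0, noise_sd^2) noise.
    Rows are subsequently row-centered.  Returns the matrix, a ground-truth
    record (per module: gene names, true loadings, true activities) and
    module definitions — planted modules with signed weights on a fraction
    of genes, plus optional random control modules drawn from the background.

    Raises on duplicate module or gene names across specs.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise RomaError("duplicate planted module names")
    for s in specs:
        if s.n_samples != n_samples:
            raise ValueError(f"spec {s.name!r} has {s.n_samples} samples, expected {n_samples}")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_background_genes)))
    bg_names = [f"BG{str(i + 1).zfill(width)}" for i in range(n_background_genes)]
    blocks = [rng.standard_normal((n_background_genes, n_samples)) * background_sd]

    gene_ids = list(bg_names)
    truth: dict[str, dict[str, np.ndarray]] = {}
    modules: list[ModuleDefinition] = []
    seen_genes = set(bg_names)
    for spec in specs:
        gnames = [f"{spec.name}_g{str(i + 1).zfill(3)}" for i in range(spec.n_genes)]
        clash = seen_genes.intersection(gnames)
        if clash:
            raise RomaError(f"duplicate gene names across specs: {sorted(clash)[:3]}")
        seen_genes.update(gnames)
        signal = spec.true_loadings.T @ spec.true_activity
        noise = rng.standard_normal(signal.shape) * spec.noise_sd
        blocks.append(signal + noise)
        gene_ids.extend(gnames)
        truth[spec.name] = {
            "gene_names": np.array(gnames),
            "loadings": spec.true_loadings.copy(),
            "activities": spec.true_activity.copy(),
        }
        modules.append(_module_from_spec(spec, gnames))

    if n_control_modules:
        size = control_size or (specs[0].n_genes if specs else 10)
        if size > n_background_genes:
            raise RomaError("control module size exceeds the background gene count")
        for c in range(n_control_modules):
            rows = rng.choice(n_background_genes, size=size, replace=False)
            modules.append(
                ModuleDefinition(
                    f"CONTROL_{c + 1:03d}",
                    "random background gene set",
                    [ModuleGene(bg_names[r]) for r in sorted(rows)],
                )
            )

    sample_ids = [f"S{str(j + 1).zfill(3)}" for j in range(n_samples)]
    X = ExpressionMatrix(np.vstack(blocks), gene_ids, sample_ids)
    return center_rows(X), truth, modules


def _module_from_spec(spec: PlantedModuleSpec, gene_names: list[str]) -> ModuleDefinition:
    """Module definition with signed weights on the leading fraction of genes."""
    n_signed = int(round(spec.signed_fraction * spec.n_genes))
    genes = []
    lead = spec.true_loadings[0]
    for i, name in enumerate(gene_names):
        if i < n_signed and lead[i] != 0:
            genes.append(ModuleGene(name, float(np.sign(lead[i])), sign_defined=True))
        else:
            genes.append(ModuleGene(name))
    return ModuleDefinition(spec.name, f"planted module ({spec.n_factors} factor(s))", genes)


def mask_entries(X: ExpressionMatrix, fraction: float, seed: int = 0) -> ExpressionMatrix:
    """Mark ``floor(fraction * cells)`` uniformly chosen entries as missing.

    No row or column is ever fully emptied.  ``fraction`` must lie in
    ``[0, 1)``.
    """
    if not 0 <= fraction < 1:
        raise RomaError(f"mask fraction must be in [0, 1), got {fraction}")
    n_mask = int(np.floor(fraction * X.values.size))
    if n_mask == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    mask = X.missing_mask.copy()
    row_obs = (~mask).sum(axis=1)
    col_obs = (~mask).sum(axis=0)
    order = rng.permutation(X.values.size)
    masked = 0
    for flat in order:
        r, c = divmod(int(flat), X.n_samples)
        if mask[r, c] or row_obs[r] <= 1 or col_obs[c] <= 1:
            continue
        mask[r, c] = True
        row_obs[r] -= 1
        col_obs[c] -= 1
        masked += 1
        if masked == n_mask:
            break
    if masked < n_mask:
        raise RomaError(
            f"could only mask {masked} of {n_mask} entries without emptying a row or column"
        )
    vals = np.where(mask, np.nan, X.values)
    return ExpressionMatrix(vals, X.gene_ids, X.sample_ids, mask)
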