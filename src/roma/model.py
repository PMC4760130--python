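"""Model / results interface tying the whole pipeline together.

:class:`ROMA` is built from an expression matrix and a module collection;
``fit()`` runs the full workflow — optional imputation, centering, the global
center, per-module gene matching, leave-one-out outlier filtering, the
(weighted / fixed-center) PC1 fit, sign orientation, and empirical
significance against random-gene-set nulls on a log-scale size grid — and
returns a :class:`ROMAResults` carrying the module score table, the
module x sample activity matrix, per-module gene projections and diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ModuleDefinition, SampleAnnotation
from .exceptions import DegenerateModuleError, RomaError
from . import io as roma_io
from .pca import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    DEFAULT_Z_MAX,
    fit_pc1,
    orient_pc1,
    robust_filter,
)
from .preprocess import center_rows, double_center, global_center, impute_missing
from .significance import (
    ModuleScore,
    NullDistribution,
    benjamini_hochberg,
    build_size_grid,
    empirical_pvalue,
    nearest_null,
    sample_null,
)

logger = logging.getLogger(__name__)

Centering = Literal["none", "rows", "double"]


@dataclass
class RomaConfig:
    """All tunable parameters of the workflow.

    Defaults: fixed-center PC1 (the mode that also captures shifted gene
    sets), leave-one-out robust filtering at ``z_max = 3.0``, modules kept
    when at least 8 of their genes are present in the data, and K = 999
    random sets per null (attainable minimum p-value 0.001).
    """

    centering: Centering = "rows"
    mode: Literal["standard", "fixed_center"] = "fixed_center"
    robust_enabled: bool = True
    z_max: float = DEFAULT_Z_MAX
    min_module_size: int = 8
    null_K: int = 999
    null_grid: int = 10
    null_seed: int = 0
    pca_seed: int = 0
    pca_tol: float = DEFAULT_TOL
    pca_max_iter: int = DEFAULT_MAX_ITER
    impute_k_rank: int | None = None
    impute_tol: float = 1e-8
    impute_max_iter: int = 1000
    casefold_genes: bool = False

    def __post_init__(self) -> None:
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.z_max <= 0:
            raise ValueError("z_max must be > 0")
        if self.null_K < 1:
            raise ValueError("null_K must be >= 1")
        if self.centering not in ("none", "rows", "double"):
            raise ValueError(f"unknown centering {self.centering!r}")
        if self.mode not in ("standard", "fixed_center"):
            raise ValueError(f"unknown mode {self.mode!r}")


class ROMA:
    """Module-activity model over one expression dataset.

    Parameters
    ----------
    expression
        Genes x samples :class:`ExpressionMatrix` (log-scale assumed).
    modules
        Module definitions (gene sets, optionally with signed weights).
    annotation
        Optional per-sample annotation used by the two-group comparison.
    config
        :class:`RomaConfig`; keyword overrides may be passed instead.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        modules: Sequence[ModuleDefinition],
        annotation: SampleAnnotation | None = None,
        config: RomaConfig | None = None,
        **overrides,
    ) -> None:
        if not modules:
            raise RomaError("no modules supplied")
        self.expression = expression
        self.modules = list(modules)
        self.annotation = annotation
        cfg = config or RomaConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        gmt_path: str | Path,
        annotation_path: str | Path | None = None,
        config: RomaConfig | None = None,
        **overrides,
    ) -> "ROMA":
        """Build the model straight from the tab-delimited input files."""
        X = roma_io.read_expression(expression_path)
        modules = roma_io.read_gmt(gmt_path)
        ann = roma_io.read_annotation(annotation_path) if annotation_path else None
        return cls(X, modules, ann, config, **overrides)

    # ------------------------------------------------------------------
    def _preprocess(self) -> tuple[ExpressionMatrix, np.ndarray]:
        cfg = self.config
        X = self.expression
        if X.has_missing:
            if cfg.impute_k_rank is None:
                raise RomaError(
                    "expression matrix has missing values; set impute_k_rank to impute them"
                )
            X = impute_missing(X, cfg.impute_k_rank, cfg.impute_tol, cfg.impute_max_iter)
        if cfg.centering == "rows":
            X = center_rows(X)
        elif cfg.centering == "double":
            X = double_center(X)
        C = global_center(X)
        return X, C

    def _match_genes(
        self, X: ExpressionMatrix, module: ModuleDefinition
    ) -> tuple[list[int], ModuleDefinition | None]:
        """Row indices of the module's genes plus the matched module.

        The returned module's gene names are the dataset-side identifiers
        (relevant under case folding) with the original weights and signs.
        """
        from .containers import ModuleGene

        index = X.gene_index()
        folded = (
            {g.upper(): i for g, i in index.items()} if self.config.casefold_genes else None
        )
        rows: list[int] = []
        matched: list[ModuleGene] = []
        for gene in module.genes:
            if folded is None:
                row = index.get(gene.name)
            else:
                row = folded.get(gene.name.upper())
            if row is None or row in rows:
                continue
            rows.append(row)
            matched.append(
                ModuleGene(X.gene_ids[row], gene.weight, gene.sign_defined)
            )
        if not matched:
            return rows, None
        return rows, ModuleDefinition(module.name, module.description, matched)

    # ------------------------------------------------------------------
    def fit(self) -> "ROMAResults":
        """Run the full workflow and return the results object."""
        cfg = self.config
        X, C = self._preprocess()
        center = C if cfg.mode == "fixed_center" else None

        fitted: list[dict] = []
        skipped: dict[str, str] = {}
        match_counts: dict[str, int] = {}
        for module in self.modules:
            rows, mod_matched = self._match_genes(X, module)
            match_counts[module.name] = len(rows)
            if len(rows) < cfg.min_module_size or mod_matched is None:
                reason = f"{len(rows)} matched genes < min_module_size {cfg.min_module_size}"
                skipped[module.name] = reason
                logger.info("skipping module %s: %s", module.name, reason)
                continue
            matched_names = mod_matched.gene_names
            X_mod = X.values[rows]
            weights = mod_matched.weights()

            if cfg.robust_enabled and len(rows) >= 3:
                keep, report = robust_filter(
                    X_mod, weights, mode=cfg.mode, center=center, z_max=cfg.z_max,
                    seed=cfg.pca_seed, tol=cfg.pca_tol, max_iter=cfg.pca_max_iter,
                    gene_names=matched_names,
                )
            else:
                keep = np.arange(len(rows))
                report = None
            if keep.size < 2:
                reason = f"only {keep.size} genes retained after outlier removal"
                skipped[module.name] = reason
                logger.warning("skipping module %s: %s", module.name, reason)
                continue

            kept_names = [matched_names[i] for i in keep]
            try:
                fit = fit_pc1(
                    X_mod[keep], weights[keep], mode=cfg.mode, center=center,
                    seed=cfg.pca_seed, tol=cfg.pca_tol, max_iter=cfg.pca_max_iter,
                    gene_names=kept_names,
                )
            except DegenerateModuleError as exc:
                skipped[module.name] = str(exc)
                logger.warning("skipping module %s: %s", module.name, exc)
                continue
            fit = orient_pc1(fit, mod_matched)
            fitted.append(
                {
                    "module": module,
                    "matched_names": matched_names,
                    "weights": weights,
                    "keep": keep,
                    "report": report,
                    "fit": fit,
                }
            )
            logger.info(
                "module %s: %d/%d genes, %d outliers removed, L1=%.4f (%d iterations)",
                module.name, keep.size, module.size,
                len(report.removed_genes) if report else 0, fit.L1, fit.n_iter,
            )

        if not fitted:
            counts = ", ".join(f"{k}={v}" for k, v in match_counts.items())
            raise RomaError(f"no module passed the size filter (matched genes: {counts})")

        # nulls over the retained-size range, shared via the log-scale grid
        sizes = [int(rec["keep"].size) for rec in fitted]
        grid = build_size_grid(min(sizes), max(sizes), cfg.null_grid)
        nulls: dict[int, NullDistribution] = {}
        for gsize in grid:
            nulls[gsize] = sample_null(
                X, gsize, cfg.null_K, mode=cfg.mode, center=center,
                seed=cfg.null_seed, tol=cfg.pca_tol, max_iter=cfg.pca_max_iter,
            )
            logger.info("null distribution for size %d: K=%d", gsize, cfg.null_K)

        scores: list[ModuleScore] = []
        projections: dict[str, pd.DataFrame] = {}
        for rec in fitted:
            module: ModuleDefinition = rec["module"]
            fit = rec["fit"]
            keep = rec["keep"]
            null = nearest_null(int(keep.size), nulls)
            p_l1 = empirical_pvalue(fit.L1, null.l1_samples)
            p_ratio = empirical_pvalue(fit.ratio, null.ratio_samples)
            report = rec["report"]
            outliers = list(report.removed_genes) if report else []
            scores.append(
                ModuleScore(
                    module=module.name,
                    size_in_file=module.size,
                    size_effective=int(keep.size),
                    L1=fit.L1,
                    p_L1=p_l1,
                    ratio=fit.ratio,
                    p_ratio=p_ratio,
                    activity=fit.activity,
                    outliers=outliers,
                    null_size=null.size,
                )
            )
            logger.info(
                "module %s scored against null size %d: p_L1=%.4g p_ratio=%.4g",
                module.name, null.size, p_l1, p_ratio,
            )
            projections[module.name] = _projection_table(rec)

        q_l1 = benjamini_hochberg([s.p_L1 for s in scores])
        q_ratio = benjamini_hochberg([s.p_ratio for s in scores])
        for s, q1, q2 in zip(scores, q_l1, q_ratio):
            s.q_L1 = float(q1)
            s.q_ratio = float(q2)

        activity = pd.DataFrame(
            np.vstack([s.activity for s in scores]),
            index=[s.module for s in scores],
            columns=X.sample_ids,
        )
        return ROMAResults(
            model=self,
            scores=scores,
            activity=activity,
            projections=projections,
            skipped=skipped,
            match_counts=match_counts,
            preprocessed=X,
            global_center=C,
            nulls=nulls,
        )


def _projection_table(rec: dict) -> pd.DataFrame:
    """Per-gene table over all matched genes; outliers carry NaN projections."""
    matched = rec["matched_names"]
    weights = rec["weights"]
    keep = set(int(i) for i in rec["keep"])
    fit = rec["fit"]
    pos = {name: j for j, name in enumerate(fit.gene_names)}
    rows = []
    for i, name in enumerate(matched):
        if i in keep:
            j = pos[name]
            rows.append((name, weights[i], fit.loadings[j], fit.pc2_proj[j], False))
        else:
            rows.append((name, weights[i], np.nan, np.nan, True))
    return pd.DataFrame(rows, columns=roma_io.PROJECTION_COLUMNS)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ROMAResults:
    """Fitted module activities, significance and diagnostics."""

    model: ROMA
    scores: list[ModuleScore]
    activity: pd.DataFrame
    projections: dict[str, pd.DataFrame]
    skipped: dict[str, str]
    match_counts: dict[str, int]
    preprocessed: ExpressionMatrix
    global_center: np.ndarray
    nulls: dict[int, NullDistribution] = field(default_factory=dict)

    @property
    def scores_frame(self) -> pd.DataFrame:
        """Module score table as a DataFrame (one row per retained module)."""
        return pd.DataFrame(
            [
                {
                    "module": s.module,
                    "size_in_file": s.size_in_file,
                    "size_effective": s.size_effective,
                    "L1": s.L1,
                    "p_L1": s.p_L1,
                    "L1_div_L2": s.ratio,
                    "p_L1_div_L2": s.p_ratio,
                    "n_outliers": len(s.outliers),
                    "q_L1_BH": s.q_L1,
                    "q_L1_div_L2_BH": s.q_ratio,
                }
                for s in self.scores
            ],
            columns=roma_io.SCORE_COLUMNS,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        cfg = self.model.config
        X = self.model.expression
        lines = [
            "Module activity summary",
            "=" * 70,
            f"dataset: {X.n_genes} genes x {X.n_samples} samples",
            f"mode: {cfg.mode} PC1, centering={cfg.centering}, "
            f"robust z_max={cfg.z_max if cfg.robust_enabled else 'off'}",
            f"null: K={cfg.null_K} random sets per size, "
            f"grid sizes {sorted(self.nulls)}",
            f"modules: {len(self.scores)} scored, {len(self.skipped)} skipped",
        ]
        for name, reason in self.skipped.items():
            lines.append(f"  skipped {name}: {reason}")
        lines.append("-" * 70)
        lines.append(self.scores_frame.to_string(index=False, float_format="%.4g"))
        return "\n".join(lines)

    def compare_groups(
        self, feature: str, group_a: str, group_b: str
    ) -> pd.DataFrame:
        """Two-sample Kolmogorov-Smirnov comparison of activities by group."""
        if self.model.annotation is None:
            raise RomaError("no sample annotation was supplied to the model")
        return compare_groups(self.activity, self.model.annotation, feature, group_a, group_b)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the score table, activity matrix and projection tables."""
        return roma_io.write_outputs(self.scores, self.activity, self.projections, out_dir)

    def plot_activity(self, module: str, ax=None):  # pragma: no cover - visual
        """Strip plot of one module's per-sample activity scores."""
        import matplotlib.pyplot as plt

        if module not in self.activity.index:
            raise KeyError(f"module {module!r} was not scored")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        vals = self.activity.loc[module]
        ax.plot(np.arange(len(vals)), vals.to_numpy(), "o", ms=4)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("sample")
        ax.set_ylabel("activity")
        ax.set_title(module)
        return ax


def compare_groups(
    activity: pd.DataFrame,
    annotation: SampleAnnotation,
    feature: str,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-module two-sided two-sample KS test between two sample groups.

    Returns a table [module, n_a, n_b, D, p] sorted by p ascending, using the
    asymptotic KS p-value on each module's activity scores split by label.
    """
    labels = annotation.column(feature)
    common = [s for s in activity.columns if s in labels.index]
    if not common:
        raise RomaError("no activity samples found in the annotation")
    labels = labels.loc[common]
    a_samples = [s for s in common if labels[s] == group_a]
    b_samples = [s for s in common if labels[s] == group_b]
    for label, members in ((group_a, a_samples), (group_b, b_samples)):
        if label not in set(labels):
            raise RomaError(f"label {label!r} absent from feature {feature!r}")
        if len(members) < 2:
            raise RomaError(f"group {label!r} has {len(members)} samples (< 2)")
    rows = []
    for module in activity.index:
        a = activity.loc[module, a_samples].to_numpy(dtype=float)
        b = activity.loc[module, b_samples].to_numpy(dtype=float)
        res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
        rows.append((module, len(a), len(b), float(res.statistic), float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["module", "n_a", "n_b", "D", "p"])
    return table.sort_values("p", kind="stable", ignore_index=True)
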