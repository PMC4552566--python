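"""End-to-end orchestration: cohort in, ranked and classified markers out.

The workflow is the study's stepwise discovery chain: validate/exclude →
rescale + interpolate → median curves → MFC + paired testing → polynomial
signatures → hierarchical clustering + shape templates → final two-step
marker classification (predictor strength x kinetic pattern).  Every
stage's artifact is kept in the result bundle so intermediate tables can
be inspected or written to disk; a config hash ties outputs to their
parameters and reruns are deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import io as cio
from . import kinetics as kin
from . import preprocess as pre
from . import stats as bst

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage knob of the workflow, serialized with each run.

    ``recovery_position`` may be a number (default 117, the study's
    cohort median) or ``"auto"`` to estimate it from sample timestamps
    via :func:`metakin.preprocess.median_recovery_position`.
    """

    grid_step: float = 1.0
    recovery_position: float | str = 117.0
    degree: int = kin.DEFAULT_DEGREE
    alpha: float = bst.ALPHA
    moderate_cut: float = bst.MODERATE_CUT
    strong_cut: float = bst.STRONG_CUT
    min_pairs: int = bst.MIN_PAIRS
    cluster_mode: str = "relative"
    linkage: str = cl.DEFAULT_LINKAGE
    cut_height: float = cl.DEFAULT_CUT_HEIGHT
    segment_bounds: tuple[float, float, float] = kin.SEGMENT_BOUNDS
    sustained_band: float = kin.SUSTAINED_BAND
    exclusions: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 1 < self.moderate_cut <= self.strong_cut:
            raise ValueError("need 1 < moderate_cut <= strong_cut")
        if self.cluster_mode not in cl.MODES:
            raise ValueError(f"cluster_mode must be one of {cl.MODES}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segment_bounds"] = list(self.segment_bounds)
        d["exclusions"] = [list(e) for e in self.exclusions]
        return d

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    recovery_position: float
    grid: pre.Grid
    curves: dict[str, list[pre.InterpolatedCurve]]
    medians: dict[str, pre.MedianCurve]
    biomarkers: pd.DataFrame
    signatures: list[kin.KineticSignature]
    tree: cl.LinkageTree
    assignment: pd.Series
    templates: list[cl.ShapeTemplate]
    classification: pd.DataFrame
    log: list[str] = field(default_factory=list)

    @property
    def volcano(self) -> pd.DataFrame:
        return bst.volcano_table(self.biomarkers)

    @property
    def heatmap(self) -> pd.DataFrame:
        return cl.heatmap_export(self.signatures, self.tree, mode=self.config.cluster_mode)

    def signature_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.signatures:
            rows.append(
                pd.DataFrame(
                    {
                        "metabolite": s.metabolite,
                        "position": s.positions,
                        "fitted_um": s.fitted,
                        "relative_pct": s.relative,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def template_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.templates:
            rows.append(
                pd.DataFrame(
                    {
                        "cluster": t.cluster_id,
                        "pattern": t.pattern,
                        "position": t.positions,
                        "relative_pct": t.curve,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def classify_markers(
    records: pd.DataFrame, patterns: pd.Series, assignment: pd.Series
) -> pd.DataFrame:
    """Merge predictor strength with kinetic pattern into the final call.

    ``patterns`` and ``assignment`` map metabolite -> pattern label /
    cluster id.  Metabolites whose predictor class is ``none`` get the
    headline "not selected" regardless of pattern; selected ones read
    e.g. "strong predictor, late marker".  A panel mismatch between the
    three inputs raises, listing the symmetric difference.
    """
    panel = set(records["metabolite"])
    for name, other in (("patterns", set(patterns.index)), ("clusters", set(assignment.index))):
        if other != panel:
            diff = sorted(panel.symmetric_difference(other))
            raise ValueError(f"panel mismatch with {name}: {diff}")
    out = records[["metabolite", "mfc", "p_adj", "predictor_class"]].copy()
    out["pattern_class"] = out["metabolite"].map(patterns)
    out["cluster"] = out["metabolite"].map(assignment)
    out["headline"] = [
        "not selected" if pc == "none" else f"{pc} predictor, {pat} marker"
        for pc, pat in zip(out["predictor_class"], out["pattern_class"])
    ]
    return out.reset_index(drop=True)


def run_pipeline(cohort: cio.Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full discovery workflow on a validated cohort."""
    config = config or PipelineConfig()
    log: list[str] = [f"config hash {config.hash}"]

    if config.exclusions:
        cohort, n_removed = cio.apply_exclusions(cohort, config.exclusions)
        log.append(f"exclusions: blanked {n_removed} concentration value(s)")

    if config.recovery_position == "auto":
        recovery_position = pre.median_recovery_position(cohort)
        log.append(f"recovery position (timestamp median): {recovery_position:.2f}%")
    else:
        recovery_position = float(config.recovery_position)
    grid = pre.Grid(step=config.grid_step, recovery_position=recovery_position)

    curves = pre.interpolate_cohort(cohort, grid=grid)
    n_curves = sum(len(v) for v in curves.values())
    log.append(f"interpolated {n_curves} curves over {len(curves)} metabolites")
    medians = pre.extract_median_curves(curves)

    biomarkers = bst.biomarker_table(
        curves,
        medians,
        alpha=config.alpha,
        moderate_cut=config.moderate_cut,
        strong_cut=config.strong_cut,
        min_pairs=config.min_pairs,
    )
    dropped = biomarkers["n_dropped"].sum()
    if dropped:
        log.append(f"paired testing dropped {int(dropped)} subject-pairs without support")

    signatures = [kin.fit_polynomial(medians[m], degree=config.degree) for m in medians]
    patterns = pd.Series(
        {
            s.metabolite: kin.classify_kinetic_pattern(
                s.relative,
                s.positions,
                sustained_band=config.sustained_band,
                segment_bounds=config.segment_bounds,
            )
            for s in signatures
        },
        name="pattern",
    )

    distances = cl.signature_distance_matrix(signatures, mode=config.cluster_mode)
    tree = cl.hierarchical_cluster(distances, method=config.linkage)
    assignment = cl.cut_tree(tree, height=config.cut_height)
    templates = cl.derive_templates(assignment, signatures)
    log.append(f"{assignment.nunique()} clusters at cut height {config.cut_height:g}")

    classification = classify_markers(biomarkers, patterns, assignment)
    return PipelineResult(
        config=config,
        recovery_position=recovery_position,
        grid=grid,
        curves=curves,
        medians=medians,
        biomarkers=biomarkers,
        signatures=signatures,
        tree=tree,
        assignment=assignment,
        templates=templates,
        classification=classification,
        log=log,
    )


def write_bundle(result: PipelineResult, out_dir) -> list[Path]:
    """Write every tabular artifact of a run (CSV + JSON sidecars)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        cio.write_table(frame, path)
        written.append(path)

    _write(result.biomarkers, "biomarkers.csv")
    _write(result.volcano, "volcano.csv")
    _write(result.signature_frame(), "signatures.csv")
    _write(
        result.assignment.rename_axis("metabolite").reset_index(),
        "clusters.csv",
    )
    _write(result.template_frame(), "templates.csv")
    _write(result.classification, "classification.csv")
    _write(result.heatmap.rename_axis("metabolite").reset_index(), "heatmap.csv")
    sidecar = {
        "config": result.config.to_dict(),
        "config_hash": result.config.hash,
        "recovery_position": result.recovery_position,
        "coefficients": {
            s.metabolite: [float(c) for c in s.coefficients] for s in result.signatures
        },
        "tree": cl.tree_to_dict(result.tree),
        "log": result.log,
    }
    path = out / "run.json"
    path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    written.append(path)
    return written


def render_plots(result: PipelineResult, out_dir, fmt: str = "png") -> list[Path]:
    """Volcano, signature, template, heatmap and dendrogram figures.

    Static images plus their exact plotted data as CSV sidecars; a
    plotting failure degrades to data-only output with a warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    cfg = result.config
    try:
        # Volcano with the selection guides.
        fig, ax = plt.subplots(figsize=(6, 5))
        v = result.volcano
        colors = v["predictor_class"].map(
            {"none": "0.6", "moderate": "tab:blue", "strong": "tab:green"}
        )
        ax.scatter(v["log2_mfc"], v["neglog10_p"], c=colors, s=24)
        ax.axhline(-np.log10(cfg.alpha), color="tab:blue", lw=0.8)
        ax.axvline(np.log2(cfg.moderate_cut), color="tab:blue", lw=0.8)
        ax.axvline(np.log2(cfg.strong_cut), color="tab:green", lw=0.8)
        ax.set_xlabel("log2(MFC)")
        ax.set_ylabel("-log10(adjusted P)")
        ax.set_title("Maximum fold change vs significance")
        fig.tight_layout()
        p = out / f"volcano.{fmt}"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

        # Kinetic signatures, default window -20..40% with outliers noted.
        fig, ax = plt.subplots(figsize=(7, 5))
        clipped = []
        for s in result.signatures:
            ax.plot(s.positions, s.relative, lw=1)
            if s.relative.max() > 40 or s.relative.min() < -20:
                clipped.append(s.metabolite)
        ax.set_ylim(-20, 40)
        ax.set_xlabel("relative workload (%)")
        ax.set_ylabel("relative concentration change (%)")
        title = "Kinetic signatures"
        if clipped:
            title += f" (beyond range: {', '.join(clipped)})"
        ax.set_title(title, fontsize=9)
        fig.tight_layout()
        p = out / f"signatures.{fmt}"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

        # Shape templates.
        fig, ax = plt.subplots(figsize=(7, 5))
        for t in result.templates:
            ax.plot(t.positions, t.curve, lw=1.5, label=f"{t.cluster_id}: {t.pattern}")
        ax.legend(fontsize=8)
        ax.set_xlabel("relative workload (%)")
        ax.set_ylabel("relative concentration change (%)")
        ax.set_title("Kinetic shape templates")
        fig.tight_layout()
        p = out / f"templates.{fmt}"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

        # Heatmap, rows in leaf order.
        hm = result.heatmap
        fig, ax = plt.subplots(figsize=(7, 0.25 * len(hm) + 2))
        im = ax.imshow(hm.to_numpy(), aspect="auto", cmap="RdYlBu_r")
        ax.set_yticks(range(len(hm)), hm.index, fontsize=7)
        ax.set_xlabel("relative workload (%)")
        fig.colorbar(im, ax=ax, label="row-scaled signature")
        fig.tight_layout()
        p = out / f"heatmap.{fmt}"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

        # Dendrogram with the cut height.
        if len(result.tree.labels) > 1:
            fig, ax = plt.subplots(figsize=(8, 5))
            dendrogram(
                result.tree.merges,
                labels=list(result.tree.labels),
                ax=ax,
                leaf_rotation=90,
                leaf_font_size=7,
            )
            ax.axhline(cfg.cut_height, color="tab:red", lw=0.8, ls="--")
            ax.set_ylabel("merge height")
            fig.tight_layout()
            p = out / f"dendrogram.{fmt}"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)
    except Exception as exc:  # pragma: no cover - plotting must never kill a run
        logger.warning("plot rendering failed (%s); tabular outputs unaffected", exc)
    return written
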