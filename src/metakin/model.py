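"""Model/Results interface over the kinetic biomarker workflow.

`KineticProfileModel` is built from a tidy cohort table (statsmodels
style); `fit()` runs the full discovery chain and returns a
`KineticProfileResults` holding the estimates — the MFC/significance
ranking, polynomial kinetic signatures, cluster assignment, shape
templates and final marker classification — with a `summary()` table and
plotting methods.
"""

from __future__ import annotations

import pandas as pd

from .io import Cohort
from .pipeline import PipelineConfig, PipelineResult, render_plots, run_pipeline, write_bundle


class KineticProfileModel:
    """Kinetic profiling of a longitudinal metabolite cohort.

    Parameters
    ----------
    cohort
        A validated :class:`~metakin.io.Cohort`.
    config
        Stage knobs; defaults reproduce the reference analysis (grid
        step 1, recovery at 117%, degree-9 signatures, MFC cuts
        1.20/1.40 at adjusted P < 0.001, complete-linkage Euclidean
        clustering of relative curves cut at height 35).
    """

    def __init__(self, cohort: Cohort, config: PipelineConfig | None = None) -> None:
        self.cohort = cohort
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, config: PipelineConfig | None = None, metadata=None
    ) -> "KineticProfileModel":
        """Build the model from a tidy cohort DataFrame (validates it)."""
        return cls(Cohort(data, metadata=metadata), config=config)

    def fit(self) -> "KineticProfileResults":
        return KineticProfileResults(self, run_pipeline(self.cohort, self.config))


class KineticProfileResults:
    """Fitted kinetic profiles and the derived biomarker classification."""

    def __init__(self, model: KineticProfileModel, result: PipelineResult) -> None:
        self.model = model
        self._result = result

    # -- estimates -------------------------------------------------------------

    @property
    def biomarkers(self) -> pd.DataFrame:
        """MFC ranking with raw/adjusted P and predictor class."""
        return self._result.biomarkers

    @property
    def signatures(self):
        """Fitted :class:`~metakin.kinetics.KineticSignature` objects."""
        return self._result.signatures

    @property
    def clusters(self) -> pd.Series:
        return self._result.assignment

    @property
    def templates(self):
        return self._result.templates

    @property
    def classification(self) -> pd.DataFrame:
        return self._result.classification

    @property
    def volcano(self) -> pd.DataFrame:
        return self._result.volcano

    @property
    def recovery_position(self) -> float:
        return self._result.recovery_position

    @property
    def log(self) -> list[str]:
        return self._result.log

    @property
    def pipeline_result(self) -> PipelineResult:
        """The raw stage-by-stage artifact bundle."""
        return self._result

    # -- presentation ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable run summary: panel ranking and final calls."""
        r = self._result
        n_subjects = max((len(v) for v in r.curves.values()), default=0)
        lines = [
            "Kinetic biomarker profile",
            "=" * 70,
            f"metabolites: {len(r.medians)}   subjects (max per metabolite): {n_subjects}",
            f"grid: step {r.grid.step:g}, recovery at {r.recovery_position:g}% "
            f"({len(r.grid)} points)   signature degree: {r.config.degree}",
            f"clusters: {r.assignment.nunique()} at cut height {r.config.cut_height:g} "
            f"({r.config.linkage} linkage, {r.config.cluster_mode} curves)",
            "-" * 70,
            f"{'metabolite':<34}{'MFC':>6}{'adj. P':>10}  classification",
            "-" * 70,
        ]
        table = r.classification.sort_values("mfc", ascending=False)
        for _, row in table.iterrows():
            p = f"{row['p_adj']:.2e}" if pd.notna(row["p_adj"]) else "--"
            lines.append(
                f"{row['metabolite']:<34}{row['mfc']:>6.2f}{p:>10}  {row['headline']}"
            )
        lines.append("-" * 70)
        return "\n".join(lines)

    def save(self, out_dir):
        """Write all tabular artifacts (CSV + JSON sidecar) to a directory."""
        return write_bundle(self._result, out_dir)

    def plot(self, out_dir, fmt: str = "png"):
        """Render volcano/signature/template/heatmap/dendrogram figures."""
        return render_plots(self._result, out_dir, fmt=fmt)
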