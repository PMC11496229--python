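"""Model/Results interface for statistical implication analysis.

:class:`ImplicationAnalysis` is built from an outcome table (a DataFrame, an
:class:`~siakit.data.OutcomeMatrix`, or a CSV via :meth:`from_csv`); its
:meth:`fit` runs the bootstrap over every ordered outcome pair — and within
strata when requested — and returns an :class:`ImplicationResults` object
carrying the directed estimates, their confidence intervals, the pair
classifications and the implication graph.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .data import FilterReport, OutcomeMatrix, complete_case_filter, read_outcomes
from .graphs import PairClassification, build_graph, classify_pairs, export_graph
from .inference import (
    BootstrapConfig,
    ImplicationResult,
    analyze_all_pairs,
    results_to_frame,
    stratified_analysis,
    write_results_csv,
)

__all__ = ["ImplicationAnalysis", "ImplicationResults"]


class ImplicationAnalysis:
    """Directed implication model over a set of binary outcomes.

    Parameters
    ----------
    data : OutcomeMatrix or pandas.DataFrame
        Binary outcome table. A DataFrame is interpreted with its index as
        subject ids and the given columns as outcomes.
    outcomes : list of str, optional
        Outcome columns to analyze (DataFrame input only; defaults to all
        non-stratum columns).
    strata : str, optional
        Name of a binary stratification column.
    drop_incomplete : bool, default True
        Apply the complete-case inclusion rule (subjects enter the analysis
        only if every outcome is observed). The count of dropped subjects is
        available as ``filter_report``.
    """

    def __init__(self, data, outcomes=None, strata=None, drop_incomplete=True):
        if isinstance(data, OutcomeMatrix):
            matrix = data
        elif isinstance(data, pd.DataFrame):
            matrix = OutcomeMatrix.from_frame(data, outcome_columns=outcomes,
                                              strata_column=strata)
        else:
            raise TypeError("data must be an OutcomeMatrix or a pandas DataFrame")
        self.filter_report: FilterReport
        if drop_incomplete:
            self.matrix, self.filter_report = complete_case_filter(matrix)
        else:
            self.matrix = matrix
            self.filter_report = FilterReport(matrix.n, matrix.n)

    @classmethod
    def from_csv(cls, path, id_column, outcome_columns, strata_column=None,
                 delimiter=",", drop_incomplete=True, **read_kwargs):
        """Build the model straight from a CSV of 0/1 outcomes."""
        matrix = read_outcomes(path, id_column, list(outcome_columns),
                               strata_column=strata_column, delimiter=delimiter,
                               **read_kwargs)
        return cls(matrix, drop_incomplete=drop_incomplete)

    @property
    def outcome_names(self) -> list[str]:
        return self.matrix.outcome_names

    @property
    def nobs(self) -> int:
        return self.matrix.n

    def fit(self, n_replicates: int = 2000, level: float = 0.95, seed: int = 0,
            smoothing: float = 0.5, bonferroni: bool = False,
            stratified: bool = False) -> "ImplicationResults":
        """Bootstrap every ordered pair and return the results object.

        ``stratified=True`` additionally re-runs the analysis within each
        level of the stratum column (which must have been declared).
        """
        cfg = BootstrapConfig(n_replicates=n_replicates, level=level, seed=seed,
                              smoothing=smoothing, bonferroni=bonferroni)
        overall = analyze_all_pairs(self.matrix, cfg)
        by_stratum = None
        if stratified:
            by_stratum = stratified_analysis(self.matrix, cfg)
        return ImplicationResults(self, cfg, overall, by_stratum)


class ImplicationResults:
    """Fitted implication analysis: estimates, CIs, classifications, graph."""

    def __init__(self, model: ImplicationAnalysis, cfg: BootstrapConfig,
                 results: list[ImplicationResult],
                 by_stratum: dict[str, list[ImplicationResult]] | None = None):
        self.model = model
        self.config = cfg
        self.results = results
        self.by_stratum = by_stratum or {}

    # -- tabular views ------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """All results (overall + strata) in the canonical column order."""
        blocks = [results_to_frame(self.results)]
        for label in sorted(self.by_stratum):
            blocks.append(results_to_frame(self.by_stratum[label]))
        return pd.concat(blocks, ignore_index=True)

    def to_csv(self, path) -> None:
        """Write the results CSV with full run provenance in its header."""
        all_results = list(self.results)
        for label in sorted(self.by_stratum):
            all_results.extend(self.by_stratum[label])
        write_results_csv(all_results, path, provenance=self.provenance())

    def provenance(self) -> dict:
        return {
            "package": f"siakit {__version__}",
            "seed": self.config.seed,
            "n_replicates": self.config.n_replicates,
            "smoothing": self.config.smoothing,
            "level": self.config.level,
            "bonferroni": self.config.bonferroni,
            "n_subjects": self.model.nobs,
            "n_dropped_incomplete": self.model.filter_report.n_dropped,
        }

    # -- graph views ---------------------------------------------------------
    def classifications(self, stratum: str | None = None) -> list[PairClassification]:
        return classify_pairs(self._select(stratum))

    def graph(self, stratum: str | None = None):
        return build_graph(self._select(stratum))

    def export_graph(self, fmt: str = "dot", stratum: str | None = None) -> str:
        return export_graph(self.graph(stratum), fmt)

    def _select(self, stratum: str | None) -> list[ImplicationResult]:
        if stratum is None:
            return self.results
        try:
            return self.by_stratum[stratum]
        except KeyError:
            raise KeyError(
                f"no stratified results for {stratum!r}; "
                f"available: {sorted(self.by_stratum)}"
            ) from None

    # -- text report ----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable report in the spirit of statsmodels summaries."""
        cfg = self.config
        pct = 100 * cfg.level
        lines = [
            "Statistical Implication Analysis (bootstrap percentile CIs)",
            "=" * 78,
            f"subjects: {self.model.nobs}   "
            f"dropped (incomplete): {self.model.filter_report.n_dropped}   "
            f"outcomes: {len(self.model.outcome_names)}",
            f"replicates: {cfg.n_replicates}   smoothing alpha: {cfg.smoothing}   "
            f"CI level: {pct:g}%   seed: {cfg.seed}",
            "-" * 78,
            f"{'source':<14}{'target':<14}{'iota':>8}{'ci_low':>9}{'ci_high':>9}"
            f"{'sig':>5}{'phi':>8}{'b':>5}",
            "-" * 78,
        ]
        def block(results, title=None):
            if title:
                lines.append(f"[{title}]")
            for r in results:
                star = "*" if r.significant else ""
                phi = f"{r.gras_intensity:.3f}" if np.isfinite(r.gras_intensity) else "--"
                lines.append(
                    f"{r.source:<14}{r.target:<14}{r.iota:>8.3f}{r.ci_low:>9.3f}"
                    f"{r.ci_high:>9.3f}{star:>5}{phi:>8}{r.b:>5}"
                )
        block(self.results)
        for label in sorted(self.by_stratum):
            lines.append("-" * 78)
            block(self.by_stratum[label], title=label)
        lines.append("-" * 78)
        lines.append("* CI excludes 0. phi: counterexample-rarity intensity. "
                     "b: counterexamples.")
        return "\n".join(lines)

    def __repr__(self) -> str:
        k = len(self.results)
        return (f"<ImplicationResults: {k} directed pairs, "
                f"{sum(r.significant for r in self.results)} significant>")
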