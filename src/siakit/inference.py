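"""Bootstrap inference for directed implication indices.

Significance of a directed implication is judged by a case-resampling
bootstrap: subjects are resampled with replacement, the smoothed iota index
is recomputed on each replicate's fourfold table, and the percentile
confidence interval is checked against zero. Each ordered pair (and each
stratum) gets its own deterministic random substream derived from the root
seed and the pair labels, so results do not depend on analysis order and do
not shift when further outcomes are added.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import OutcomeMatrix, complete_case_filter
from .tables import crosstab, gras_intensity, _iota_from_counts, iota

logger = logging.getLogger(__name__)

#: exact column order of the results CSV
RESULT_COLUMNS = [
    "source", "target", "stratum", "n", "a", "b", "c", "d",
    "iota", "ci_low", "ci_high", "significant", "gras_intensity",
    "degenerate_fraction", "n_replicates", "seed",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the percentile bootstrap.

    ``level`` is the two-sided confidence level (0.95 gives the 95% CI whose
    exclusion of zero defines significance at the 0.05 level). ``smoothing``
    is the per-cell pseudo-count passed through to the index.
    """

    n_replicates: int = 2000
    level: float = 0.95
    seed: int = 0
    smoothing: float = 0.5
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        if not self.smoothing > 0:
            raise ValueError("smoothing pseudo-count must be positive")


@dataclass(frozen=True)
class ImplicationResult:
    """Directed implication estimate with bootstrap CI for one ordered pair."""

    source: str
    target: str
    n: int
    a: int
    b: int
    c: int
    d: int
    iota: float
    ci_low: float
    ci_high: float
    significant: bool
    gras_intensity: float  # NaN when a margin is empty
    degenerate_margin: bool
    degenerate_fraction: float
    n_replicates: int
    seed: int
    stratum: str | None = None


def _substream(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-pair/per-stratum RNG derived from the root seed.

    Label hashes (CRC-32, platform-independent) enter the seed sequence, so
    the stream for a given (source, target, stratum) never depends on which
    other pairs are analyzed or in what order.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(lab.encode("utf-8")) & 0x7FFFFFFF for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _bootstrap_tables(x: np.ndarray, y: np.ndarray, n_replicates: int,
                      rng: np.random.Generator):
    """Cell counts (a, b, c, d) of case-resampled replicates, vectorized."""
    n = x.size
    idx = rng.integers(0, n, size=(n_replicates, n))
    xs = x[idx]
    ys = y[idx]
    a = (xs & ys).sum(axis=1)
    b = (xs & ~ys).sum(axis=1)
    c = (~xs & ys).sum(axis=1)
    d = n - a - b - c
    return a, b, c, d


def bootstrap_pair(
    m: OutcomeMatrix,
    source: str,
    target: str,
    cfg: BootstrapConfig,
    stratum: str | None = None,
    level: float | None = None,
) -> ImplicationResult:
    """Estimate iota(source => target) with a percentile bootstrap CI.

    Subjects (rows) are the resampling unit. Replicates in which a column
    becomes constant are kept — smoothing keeps the index finite — and their
    fraction is reported, since a high fraction signals a margin too thin to
    resample reliably.
    """
    x = m.column(source)
    y = m.column(target)
    keep = ~(np.isnan(x) | np.isnan(y))
    x = x[keep].astype(bool)
    y = y[keep].astype(bool)
    n = int(x.size)
    if n < 2:
        raise ValueError(f"need at least 2 complete rows for ({source}, {target}), got {n}")

    t = crosstab(m.take(keep), source, target)
    point = iota(t, cfg.smoothing)

    rng = _substream(cfg.seed, source, target, *(() if stratum is None else (stratum,)))
    a, b, c, d = _bootstrap_tables(x, y, cfg.n_replicates, rng)
    boot = _iota_from_counts(a, b, c, d, cfg.smoothing)
    degenerate = (np.minimum.reduce([a + b, c + d, a + c, b + d]) == 0)

    lvl = cfg.level if level is None else level
    lo, hi = np.quantile(boot, [(1 - lvl) / 2, 1 - (1 - lvl) / 2])

    try:
        phi = gras_intensity(t)
    except ValueError:
        phi = float("nan")

    return ImplicationResult(
        source=source,
        target=target,
        n=n,
        a=t.a, b=t.b, c=t.c, d=t.d,
        iota=point,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        gras_intensity=phi,
        degenerate_margin=t.degenerate_margin,
        degenerate_fraction=float(degenerate.mean()),
        n_replicates=cfg.n_replicates,
        seed=cfg.seed,
        stratum=stratum,
    )


def analyze_all_pairs(
    m: OutcomeMatrix,
    cfg: BootstrapConfig,
    stratum: str | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> list[ImplicationResult]:
    """Directed implication analysis of every ordered outcome pair.

    k outcomes yield k(k-1) results. With ``cfg.bonferroni`` the per-pair
    confidence level is raised to 1 - 0.05/#pairs (off by default: the
    reference analysis reports all directed tests at the nominal 0.05
    level without correction).
    """
    if len(m.outcome_names) < 2:
        raise ValueError("need at least 2 outcomes for a pairwise analysis")
    if pairs is None:
        pairs = [(s, t) for s in m.outcome_names for t in m.outcome_names if s != t]
    level = cfg.level
    if cfg.bonferroni and pairs:
        level = 1 - (1 - cfg.level) / len(pairs)
    return [
        bootstrap_pair(m, s, t, cfg, stratum=stratum, level=level)
        for s, t in pairs
    ]


def stratified_analysis(
    m: OutcomeMatrix,
    cfg: BootstrapConfig,
    pairs: list[tuple[str, str]] | None = None,
) -> dict[str, list[ImplicationResult]]:
    """Re-run the all-pairs analysis separately within each stratum.

    The matrix must carry a binary stratum. Rows with a missing stratum are
    excluded. A stratum with fewer than 2 rows is skipped with a warning
    rather than raising, since a thin subgroup is a property of the data,
    not a caller error.
    """
    if m.strata is None:
        raise ValueError("matrix has no stratum variable")
    out: dict[str, list[ImplicationResult]] = {}
    for value in (0.0, 1.0):
        label = f"{m.strata_name}={int(value)}"
        mask = m.strata == value
        if mask.sum() < 2:
            logger.warning(
                "stratum %s has %d row(s) (< 2): skipped", label, int(mask.sum())
            )
            continue
        sub = m.take(mask)
        out[label] = analyze_all_pairs(sub, cfg, stratum=label, pairs=pairs)
    return out


def results_to_frame(results: list[ImplicationResult]) -> pd.DataFrame:
    """Results as a DataFrame with the canonical column order."""
    rows = []
    for r in results:
        rows.append({
            "source": r.source,
            "target": r.target,
            "stratum": "" if r.stratum is None else r.stratum,
            "n": r.n,
            "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "iota": r.iota,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "significant": r.significant,
            "gras_intensity": r.gras_intensity,
            "degenerate_fraction": r.degenerate_fraction,
            "n_replicates": r.n_replicates,
            "seed": r.seed,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_csv(results: list[ImplicationResult], path,
                      provenance: dict | None = None) -> None:
    """Write results to CSV, prefixed with ``# key=value`` provenance lines."""
    frame = results_to_frame(results)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")
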