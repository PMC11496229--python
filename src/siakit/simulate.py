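"""Synthetic binary cohorts with planted implicative structure.

Since clinical cohorts behind implication analyses are rarely shareable,
every stage of the package is exercised on generated data with *known*
directed structure. The generator is conditional: a link
``source -> target`` with counterexample rate ``epsilon`` and baseline rate
``q`` means ``P(target=1 | source=1) = 1 - epsilon`` and
``P(target=1 | source=0) = q``. Root outcomes are independent Bernoulli
draws at their baseline probability. When several links point at one
target they combine by noisy-OR: each link is an independent causal channel
that turns the target on with probability ``1 - epsilon`` when its source is
present and ``q`` when absent, so counterexamples stay rare whenever any
source is present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import OutcomeMatrix

__all__ = [
    "LinkSpec", "StratumSpec", "SyntheticCohortSpec",
    "generate_cohort", "generate_independence", "recovery_experiment",
    "study_like_spec",
]


@dataclass(frozen=True)
class LinkSpec:
    """A planted directed implication between two outcomes."""

    source: str
    target: str
    epsilon: float  # counterexample rate P(target=0 | source=1)
    q: float        # baseline rate P(target=1 | source=0)

    def __post_init__(self) -> None:
        for name in ("epsilon", "q"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.source == self.target:
            raise ValueError(f"self-link on {self.source!r}")


@dataclass(frozen=True)
class StratumSpec:
    """Optional binary baseline covariate, with optional per-level links.

    When ``links_by_level`` is given, subjects in stratum level 0/1 are
    generated under that level's link list (outcome set and baselines are
    shared), emulating implications that hold in one baseline subgroup only.
    """

    name: str
    prevalence: float
    links_by_level: dict[int, tuple[LinkSpec, ...]] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if self.links_by_level is not None:
            lbl = {int(k): tuple(v) for k, v in self.links_by_level.items()}
            if set(lbl) != {0, 1}:
                raise ValueError("links_by_level must map exactly the levels 0 and 1")
            object.__setattr__(self, "links_by_level", lbl)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full recipe for one synthetic cohort.

    ``baselines`` gives the Bernoulli probability of every *root* outcome
    (an outcome with no incoming link); linked targets take their law from
    their links. ``outcomes`` fixes the column order.
    """

    n: int
    outcomes: tuple[str, ...]
    baselines: dict[str, float]
    links: tuple[LinkSpec, ...] = ()
    stratum: StratumSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "links", tuple(self.links))
        if len(set(self.outcomes)) != len(self.outcomes):
            raise ValueError("outcome names must be unique")
        for p in self.baselines.values():
            if not 0 <= p <= 1:
                raise ValueError(f"baseline probability {p} outside [0, 1]")
        for links in self._link_sets():
            self._validate_links(links)

    def _link_sets(self) -> list[tuple[LinkSpec, ...]]:
        if self.stratum is not None and self.stratum.links_by_level is not None:
            return [self.stratum.links_by_level[0], self.stratum.links_by_level[1]]
        return [self.links]

    def _validate_links(self, links: tuple[LinkSpec, ...]) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.outcomes)
        for link in links:
            for end in (link.source, link.target):
                if end not in self.outcomes:
                    raise ValueError(f"link endpoint {end!r} is not a declared outcome")
            g.add_edge(link.source, link.target)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"links must be acyclic; found cycle {cycle}")
        for name in self.outcomes:
            if g.in_degree(name) == 0 and name not in self.baselines:
                raise ValueError(f"root outcome {name!r} needs a baseline probability")

    def generation_order(self, links: tuple[LinkSpec, ...]) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.outcomes)
        g.add_edges_from((l.source, l.target) for l in links)
        # stable topological order: break ties by declared column order
        order_index = {name: i for i, name in enumerate(self.outcomes)}
        return list(nx.lexicographical_topological_sort(g, key=order_index.get))

    # -- JSON round-trip ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "n": self.n,
            "outcomes": list(self.outcomes),
            "baselines": dict(self.baselines),
            "links": [vars(l) for l in self.links],
            "seed": self.seed,
        }
        if self.stratum is not None:
            st = {"name": self.stratum.name, "prevalence": self.stratum.prevalence}
            if self.stratum.links_by_level is not None:
                st["links_by_level"] = {
                    str(k): [vars(l) for l in v]
                    for k, v in self.stratum.links_by_level.items()
                }
            payload["stratum"] = st
        return json.dumps(payload, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "SyntheticCohortSpec":
        raw = json.loads(text)
        stratum = None
        if "stratum" in raw and raw["stratum"] is not None:
            st = raw["stratum"]
            lbl = None
            if st.get("links_by_level") is not None:
                lbl = {int(k): tuple(LinkSpec(**l) for l in v)
                       for k, v in st["links_by_level"].items()}
            stratum = StratumSpec(name=st["name"], prevalence=st["prevalence"],
                                  links_by_level=lbl)
        return cls(
            n=raw["n"],
            outcomes=tuple(raw["outcomes"]),
            baselines={k: float(v) for k, v in raw.get("baselines", {}).items()},
            links=tuple(LinkSpec(**l) for l in raw.get("links", [])),
            stratum=stratum,
            seed=int(raw.get("seed", 0)),
        )


def _generate_block(spec: SyntheticCohortSpec, links: tuple[LinkSpec, ...],
                    n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw one block of subjects under a single link list."""
    incoming: dict[str, list[LinkSpec]] = {name: [] for name in spec.outcomes}
    for link in links:
        incoming[link.target].append(link)
    cols: dict[str, np.ndarray] = {}
    for name in spec.generation_order(links):
        if not incoming[name]:
            p = np.full(n, spec.baselines[name])
        else:
            # noisy-OR of independent causal channels
            p_off = np.ones(n)
            for link in incoming[name]:
                src = cols[link.source]
                p_off *= np.where(src == 1, link.epsilon, 1.0 - link.q)
            p = 1.0 - p_off
        cols[name] = (rng.random(n) < p).astype(float)
    return cols


def generate_cohort(spec: SyntheticCohortSpec,
                    seed: int | None = None) -> OutcomeMatrix:
    """Generate a cohort according to ``spec`` (deterministic given seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    strata = None
    if spec.stratum is None:
        cols = _generate_block(spec, spec.links, n, rng)
    else:
        strata = (rng.random(n) < spec.stratum.prevalence).astype(float)
        if spec.stratum.links_by_level is None:
            cols = _generate_block(spec, spec.links, n, rng)
        else:
            cols = {name: np.empty(n) for name in spec.outcomes}
            for level in (0, 1):
                mask = strata == level
                block = _generate_block(
                    spec, spec.stratum.links_by_level[level], int(mask.sum()), rng
                )
                for name in spec.outcomes:
                    cols[name][mask] = block[name]
    width = len(str(n))
    return OutcomeMatrix(
        subject_ids=[f"S{i + 1:0{width}d}" for i in range(n)],
        outcome_names=list(spec.outcomes),
        values=np.column_stack([cols[name] for name in spec.outcomes]),
        strata_name=None if spec.stratum is None else spec.stratum.name,
        strata=strata,
    )


def generate_independence(n: int, margins: dict[str, float],
                          seed: int = 0) -> OutcomeMatrix:
    """Null-model cohort: outcomes i.i.d. Bernoulli, independent columns."""
    rng = np.random.default_rng(seed)
    names = list(margins)
    values = np.column_stack([
        (rng.random(n) < margins[name]).astype(float) for name in names
    ])
    width = len(str(n))
    return OutcomeMatrix(
        subject_ids=[f"S{i + 1:0{width}d}" for i in range(n)],
        outcome_names=names,
        values=values,
    )


def recovery_experiment(spec: SyntheticCohortSpec, n_reps: int, cfg,
                        master_seed: int = 0):
    """Repeatedly generate cohorts and measure recovery of planted links.

    For each of ``n_reps`` replications a fresh cohort is generated and the
    all-ordered-pairs bootstrap analysis is run. The summary has one row per
    directed pair with the detection (significance) rate, the mean index,
    whether the pair is a planted link, and the rate at which the pair's
    index exceeds its reverse ("direction_win_rate").
    """
    import pandas as pd

    from .inference import BootstrapConfig, analyze_all_pairs

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    planted = {(l.source, l.target) for links in spec._link_sets() for l in links}
    pairs = [(s, t) for s in spec.outcomes for t in spec.outcomes if s != t]
    detect = {p: 0 for p in pairs}
    iotas = {p: [] for p in pairs}
    wins = {p: 0 for p in pairs}
    root = np.random.SeedSequence(master_seed & 0x7FFFFFFF)
    for rep, child in enumerate(root.spawn(n_reps)):
        data_seed, boot_seed = (int(s) & 0x7FFFFFFF for s in child.generate_state(2))
        cohort = generate_cohort(spec, seed=data_seed)
        cfg_rep = BootstrapConfig(
            n_replicates=cfg.n_replicates, level=cfg.level, seed=boot_seed,
            smoothing=cfg.smoothing, bonferroni=cfg.bonferroni,
        )
        results = {(r.source, r.target): r
                   for r in analyze_all_pairs(cohort, cfg_rep, pairs=pairs)}
        for p in pairs:
            r = results[p]
            detect[p] += r.significant and r.iota > 0
            iotas[p].append(r.iota)
            wins[p] += r.iota > results[(p[1], p[0])].iota
    rows = [{
        "source": s,
        "target": t,
        "planted": (s, t) in planted,
        "detection_rate": detect[(s, t)] / n_reps,
        "mean_iota": float(np.mean(iotas[(s, t)])),
        "direction_win_rate": wins[(s, t)] / n_reps,
        "n_reps": n_reps,
    } for s, t in pairs]
    return pd.DataFrame(rows)


def study_like_spec(n: int = 219, seed: int = 0) -> SyntheticCohortSpec:
    """A cohort spec emulating a four-outcome early-intervention study.

    One hub outcome ("working") implies the three others; symptomatic and
    functional recovery are tightly coupled (rare counterexamples in both
    directions, so their implication is reciprocal); independent living is
    the most weakly attached outcome. Baseline employment is available as a
    stratum. Margins are plausible placeholders for a 36-month
    early-psychosis cohort (the reference study's exact margins are not
    public): working ~0.45, living ~0.65, symptomatic remission ~0.68,
    functional recovery ~0.80.
    """
    return SyntheticCohortSpec(
        n=n,
        outcomes=("working", "living", "symptomatic", "functional"),
        baselines={"working": 0.45},
        links=(
            LinkSpec("working", "living", epsilon=0.10, q=0.45),
            LinkSpec("working", "symptomatic", epsilon=0.05, q=0.45),
            LinkSpec("working", "functional", epsilon=0.05, q=0.25),
            LinkSpec("symptomatic", "functional", epsilon=0.10, q=0.20),
        ),
        stratum=StratumSpec(name="baseline_work", prevalence=0.30),
        seed=seed,
    )
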