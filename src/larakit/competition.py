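"""Competition-assay propagation of relative and absolute catalytic
efficiencies.

When one enzyme acts on two substrates X and Y simultaneously, the ratio of
initial rates is

    v_x / v_y = (kcat_X/KM_X)·[S_X] / ((kcat_Y/KM_Y)·[S_Y]),

so a single competition measurement yields the ratio of specificity
constants k_X/k_Y = (v_x/v_y)·([S_Y]/[S_X]) — at equal concentrations the
[S] terms cancel.  A panel of pairwise measurements forms a graph over
substrates whose edge weights are log-ratios; node values (log efficiencies)
are recovered by weighted least squares in log space, which treats redundant
and mildly inconsistent designs symmetrically (sequential multiplication
along a path is available as a comparison mode).  The solved table is
normalized to the preferred substrate (maximum = 100%) and can be anchored
to one experimentally measured kcat/KM to produce absolute values with
first-order propagated uncertainty.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "CompetitionObservation",
    "RatioEstimate",
    "RelativeEfficiencyTable",
    "AbsoluteEfficiencyTable",
    "CycleReport",
    "efficiency_ratio",
    "aggregate_ratios",
    "solve_relative_efficiencies",
    "chain_relative_efficiencies",
    "anchor_absolute",
    "cycle_consistency_report",
    "RelativeEfficiencySolver",
]


@dataclass(frozen=True)
class CompetitionObservation:
    """One pairwise competition measurement (rates in a shared arbitrary unit)."""

    enzyme: str
    substrate_x: str
    substrate_y: str
    conc_x: float  # mM
    conc_y: float  # mM
    vx: float
    vy: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.substrate_x == self.substrate_y:
            raise ValueError("competition requires two distinct substrates")
        if self.conc_x <= 0 or self.conc_y <= 0:
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class RatioEstimate:
    """k_X/k_Y for one substrate pair (geometric mean over replicates)."""

    substrate_x: str
    substrate_y: str
    ratio: float
    se_log: float | None  # standard error of log ratio; None for n = 1
    n: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RelativeEfficiencyTable:
    """Relative kcat/KM per substrate, preferred substrate = 100%."""

    enzyme: str
    values: tuple[tuple[str, float], ...]
    preferred: str
    se_log: tuple[tuple[str, float], ...]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    def se_log_dict(self) -> dict[str, float]:
        return dict(self.se_log)


@dataclass(frozen=True)
class AbsoluteEfficiencyTable:
    """Absolute kcat/KM per substrate (M⁻¹ s⁻¹) with 95% CIs."""

    enzyme: str
    values: tuple[tuple[str, float], ...]
    ci: tuple[tuple[str, tuple[float, float]], ...]
    anchor_substrate: str
    anchor_value: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    def ci_dict(self) -> dict[str, tuple[float, float]]:
        return dict(self.ci)


@dataclass(frozen=True)
class CycleReport:
    """Consistency of one independent cycle in the ratio graph."""

    cycle: tuple[str, ...]
    log_product: float
    flagged: bool


def efficiency_ratio(obs: CompetitionObservation) -> float:
    """k_X/k_Y from one observation: (vx/vy)·([S_Y]/[S_X]).

    vx = 0 (substrate X not converted) returns 0.0 — the caller excludes
    such pairs from the graph; vy = 0 is an error (reverse the pair).
    """
    if obs.vy <= 0:
        raise ValueError(
            f"vy must be positive to form a ratio "
            f"({obs.substrate_x} vs {obs.substrate_y}); swap the pair"
        )
    if obs.vx < 0:
        raise ValueError("vx must be non-negative")
    return (obs.vx / obs.vy) * (obs.conc_y / obs.conc_x)


def aggregate_ratios(
    observations: Sequence[CompetitionObservation],
) -> list[RatioEstimate]:
    """Pool replicate observations per (ordered) substrate pair.

    Returns the geometric-mean ratio and the log-scale standard error of the
    mean.  Pairs where every replicate shows vx = 0 are reported with ratio
    0 and a ``no_activity_x`` flag (to be excluded from graph solving).
    """
    groups: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for obs in observations:
        key = (obs.substrate_x, obs.substrate_y)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(efficiency_ratio(obs))
    estimates = []
    for key in order:
        ratios = groups[key]
        positive = [r for r in ratios if r > 0]
        if not positive:
            estimates.append(
                RatioEstimate(
                    substrate_x=key[0],
                    substrate_y=key[1],
                    ratio=0.0,
                    se_log=None,
                    n=len(ratios),
                    flags=("no_activity_x",),
                )
            )
            continue
        logs = np.log(positive)
        n = len(logs)
        se = float(np.std(logs, ddof=1) / math.sqrt(n)) if n > 1 else None
        estimates.append(
            RatioEstimate(
                substrate_x=key[0],
                substrate_y=key[1],
                ratio=float(np.exp(logs.mean())),
                se_log=se,
                n=n,
            )
        )
    return estimates


def _as_estimates(
    ratios: Iterable,
) -> list[RatioEstimate]:
    """Accept RatioEstimate objects or ((x, y), ratio[, se_log]) tuples."""
    out = []
    for item in ratios:
        if isinstance(item, RatioEstimate):
            out.append(item)
        else:
            (x, y), ratio, *rest = item
            se = rest[0] if rest else None
            out.append(
                RatioEstimate(substrate_x=x, substrate_y=y, ratio=ratio, se_log=se, n=1)
            )
    return out


def solve_relative_efficiencies(
    ratios: Iterable, enzyme: str = ""
) -> list[RelativeEfficiencyTable]:
    """Solve the ratio graph for relative efficiencies (preferred = 100%).

    Accepts :class:`RatioEstimate` objects or ``((x, y), ratio, se_log)``
    tuples.  On each connected component a weighted least-squares problem in
    log space is solved (weights 1/se_log², unit weights when any edge lacks
    a standard error); the solution is exponentiated and scaled so the
    maximum is exactly 100.  One table is returned per connected component;
    multiple components trigger a warning since their values are not
    comparable.  Zero-ratio edges (no detectable activity) are dropped with
    a warning; zero/negative ratios supplied directly are an error.
    """
    estimates = _as_estimates(ratios)
    if not estimates:
        raise ValueError("no ratios supplied")
    usable = []
    for est in estimates:
        if "no_activity_x" in est.flags:
            warnings.warn(
                f"substrate {est.substrate_x!r} showed no activity against "
                f"{est.substrate_y!r}; pair excluded",
                stacklevel=2,
            )
            continue
        if est.ratio <= 0:
            raise ValueError(
                f"non-positive ratio {est.ratio} for pair "
                f"({est.substrate_x}, {est.substrate_y})"
            )
        usable.append(est)
    if not usable:
        raise ValueError("no usable (positive-ratio) pairs")

    graph = nx.Graph()
    for est in usable:
        graph.add_edge(est.substrate_x, est.substrate_y)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c))
    if len(components) > 1:
        warnings.warn(
            f"ratio graph has {len(components)} disconnected components; "
            "their relative values are not mutually comparable",
            stacklevel=2,
        )

    have_all_se = all(est.se_log not in (None, 0.0) for est in usable)
    tables = []
    for nodes in components:
        index = {s: i for i, s in enumerate(nodes)}
        edges = [
            e
            for e in usable
            if e.substrate_x in index and e.substrate_y in index
        ]
        k = len(nodes)
        m = len(edges)
        # log k_x - log k_y = log ratio; node 0 fixed at 0.
        a = np.zeros((m, k))
        b = np.zeros(m)
        w = np.ones(m)
        for row, est in enumerate(edges):
            a[row, index[est.substrate_x]] = 1.0
            a[row, index[est.substrate_y]] = -1.0
            b[row] = math.log(est.ratio)
            if have_all_se:
                w[row] = 1.0 / est.se_log**2
        a_red = a[:, 1:]
        sw = np.sqrt(w)
        sol, *_ = np.linalg.lstsq(a_red * sw[:, None], b * sw, rcond=None)
        logs = np.concatenate([[0.0], sol])
        resid = a @ logs - b
        # Covariance of the solved log values (node 0 as reference).
        ata = (a_red * w[:, None]).T @ a_red
        cov_red = np.linalg.pinv(ata)
        if not have_all_se:
            dof = m - (k - 1)
            sigma2 = float(resid @ (w * resid)) / dof if dof > 0 else 0.0
            cov_red = cov_red * sigma2
        cov = np.zeros((k, k))
        cov[1:, 1:] = cov_red

        best = int(np.argmax(logs))
        # Deterministic tie-break by name among equal maxima.
        maxima = [i for i in range(k) if math.isclose(logs[i], logs[best])]
        best = min(maxima, key=lambda i: nodes[i])
        values = 100.0 * np.exp(logs - logs[best])
        values[best] = 100.0  # exact, by construction
        se_nodes = np.sqrt(
            np.maximum(
                np.diag(cov) + cov[best, best] - 2 * cov[:, best], 0.0
            )
        )
        tables.append(
            RelativeEfficiencyTable(
                enzyme=enzyme,
                values=tuple((s, float(values[i])) for s, i in index.items()),
                preferred=nodes[best],
                se_log=tuple((s, float(se_nodes[i])) for s, i in index.items()),
            )
        )
    return tables


def chain_relative_efficiencies(
    ratios: Iterable, enzyme: str = ""
) -> list[RelativeEfficiencyTable]:
    """Comparison mode: propagate ratios multiplicatively along a spanning
    tree (breadth-first) instead of least squares.  Agrees with the
    least-squares solution on consistent designs; on inconsistent ones the
    result depends on the tree, which is why least squares is the default.
    """
    estimates = [e for e in _as_estimates(ratios) if e.ratio > 0]
    if not estimates:
        raise ValueError("no usable ratios supplied")
    graph = nx.Graph()
    for est in estimates:
        graph.add_edge(est.substrate_x, est.substrate_y, log=math.log(est.ratio))
        # direction bookkeeping: log is for x over y
        graph[est.substrate_x][est.substrate_y]["x"] = est.substrate_x
    tables = []
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c))
    for nodes in comps:
        root = nodes[0]
        logs = {root: 0.0}
        for parent, child in nx.bfs_edges(graph.subgraph(nodes), root):
            edge = graph[parent][child]
            delta = edge["log"] if edge["x"] == child else -edge["log"]
            logs[child] = logs[parent] + delta
        best = max(sorted(logs), key=lambda s: logs[s])
        tables.append(
            RelativeEfficiencyTable(
                enzyme=enzyme,
                values=tuple(
                    (s, 100.0 if s == best else 100.0 * math.exp(logs[s] - logs[best]))
                    for s in nodes
                ),
                preferred=best,
                se_log=tuple((s, 0.0) for s in nodes),
            )
        )
    return tables


def anchor_absolute(
    rel: RelativeEfficiencyTable,
    anchor_substrate: str,
    anchor_value: float,
    anchor_ci: tuple[float, float] | None = None,
) -> AbsoluteEfficiencyTable:
    """Convert a relative table to absolute kcat/KM via one measured anchor.

    value(s) = anchor_value · rel(s)/rel(anchor); the anchor cell reproduces
    the measured value exactly.  95% CIs combine, to first order on the log
    scale, the anchor's relative error with the graph-propagation standard
    errors of s and of the anchor.
    """
    values = rel.as_dict()
    if anchor_substrate not in values:
        raise ValueError(
            f"anchor substrate {anchor_substrate!r} not in table "
            f"({sorted(values)})"
        )
    if anchor_value <= 0:
        raise ValueError("anchor value must be positive")
    se = rel.se_log_dict()
    se_anchor_meas = 0.0
    if anchor_ci is not None:
        lo, hi = anchor_ci
        if not (0 < lo <= anchor_value <= hi):
            raise ValueError("anchor CI must bracket the anchor value")
        se_anchor_meas = math.log(hi / lo) / (2 * 1.959963984540054)
    out_values = []
    out_ci = []
    for s, v in values.items():
        if s == anchor_substrate:
            val = anchor_value
            ci = anchor_ci if anchor_ci is not None else (val, val)
        else:
            val = anchor_value * v / values[anchor_substrate]
            se_total = math.sqrt(
                se_anchor_meas**2 + se[s] ** 2 + se[anchor_substrate] ** 2
            )
            half = 1.959963984540054 * se_total
            ci = (val * math.exp(-half), val * math.exp(half))
        out_values.append((s, val))
        out_ci.append((s, ci))
    return AbsoluteEfficiencyTable(
        enzyme=rel.enzyme,
        values=tuple(out_values),
        ci=tuple(out_ci),
        anchor_substrate=anchor_substrate,
        anchor_value=anchor_value,
    )


def cycle_consistency_report(
    ratios: Iterable, tolerance: float = 0.2
) -> list[CycleReport]:
    """Check every independent cycle of the ratio graph.

    For each cycle in a cycle basis the signed log-ratios are summed; a
    perfectly consistent design gives 0 (product of ratios 1).  Cycles with
    ``|log product| > tolerance`` are flagged.  Trees yield an empty report.
    """
    estimates = [e for e in _as_estimates(ratios) if e.ratio > 0]
    graph = nx.Graph()
    for est in estimates:
        graph.add_edge(
            est.substrate_x,
            est.substrate_y,
            log=math.log(est.ratio),
            x=est.substrate_x,
        )
    reports = []
    for cycle in nx.cycle_basis(graph):
        total = 0.0
        for i, node in enumerate(cycle):
            nxt = cycle[(i + 1) % len(cycle)]
            edge = graph[node][nxt]
            total += edge["log"] if edge["x"] == nxt else -edge["log"]
        reports.append(
            CycleReport(
                cycle=tuple(cycle),
                log_product=total,
                flagged=abs(total) > tolerance,
            )
        )
    return reports


class RelativeEfficiencySolver(BaseEstimator):
    """Estimator wrapper: observations in, relative/absolute tables out.

    ``fit`` aggregates replicate competition observations into per-pair
    ratio estimates and solves the log-space least-squares problem; the
    fitted ``table_`` (single connected component) or ``tables_`` then feeds
    :meth:`anchor`.
    """

    def __init__(self, enzyme: str = "", cycle_tolerance: float = 0.2):
        self.enzyme = enzyme
        self.cycle_tolerance = cycle_tolerance

    def fit(self, X: Sequence[CompetitionObservation], y=None):
        self.ratios_ = aggregate_ratios(list(X))
        self.tables_ = solve_relative_efficiencies(self.ratios_, enzyme=self.enzyme)
        self.cycles_ = cycle_consistency_report(
            self.ratios_, tolerance=self.cycle_tolerance
        )
        return self

    @property
    def table_(self) -> RelativeEfficiencyTable:
        if len(self.tables_) != 1:
            raise ValueError(
                f"{len(self.tables_)} disconnected tables; use .tables_"
            )
        return self.tables_[0]

    def anchor(
        self,
        anchor_substrate: str,
        anchor_value: float,
        anchor_ci: tuple[float, float] | None = None,
    ) -> AbsoluteEfficiencyTable:
        for table in self.tables_:
            if anchor_substrate in table.as_dict():
                return anchor_absolute(table, anchor_substrate, anchor_value, anchor_ci)
        raise ValueError(f"anchor substrate {anchor_substrate!r} not in any table")
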