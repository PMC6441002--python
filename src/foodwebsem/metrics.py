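"""Structural descriptors of a food web.

The descriptor set feeding the path models: species count S, link count L,
directed connectance C = L/S² (self-loops counted), the proportions of
basal / intermediate / top taxa, the prey-averaged trophic level (max and
mean), and the fraction of omnivores.

Self-loops (cannibalism) are kept in L and C but removed before trophic
level, role and omnivory computations, where they create degeneracies
(a pure cannibal would otherwise be its own prey at an undefined level).

Prey-averaged trophic level solves

    TL_i = 1 + (1/n_i) * sum_{j in prey(i)} TL_j,     TL = 1 for basal taxa,

i.e. the linear system (I - Q) TL = 1 with Q_ij = 1/n_i for j in prey(i):
every consumer is assumed to feed equally among its prey.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .webio import FoodWeb


class TrophicLevelError(RuntimeError):
    """Raised when trophic levels are undefined (consumer cycle with no
    pathway to a basal taxon)."""


@dataclass(frozen=True)
class TrophicPositions:
    """Prey-averaged trophic levels for one web.

    ``n`` holds each taxon's prey count with self-loops excluded; basal
    taxa (``n == 0``) sit exactly at level 1.
    """

    web_id: str
    TL: dict[str, float]
    n: dict[str, int]
    method: Literal["linear_solve", "damped_iteration"]
    converged: bool


@dataclass(frozen=True)
class MetricsRow:
    """One web's full descriptor vector."""

    web_id: str
    S: int
    L: int
    C: float
    p_basal: float
    p_intermediate: float
    p_top: float
    omnivory: float
    maxTL: float
    meanTL: float

    def to_dict(self) -> dict:
        return {
            "web_id": self.web_id,
            "S": self.S,
            "L": self.L,
            "C": self.C,
            "p_basal": self.p_basal,
            "p_intermediate": self.p_intermediate,
            "p_top": self.p_top,
            "omnivory": self.omnivory,
            "maxTL": self.maxTL,
            "meanTL": self.meanTL,
        }


def _prey_sets(web: FoodWeb) -> dict[str, set[str]]:
    """Per-taxon prey sets with self-loops removed."""
    prey: dict[str, set[str]] = {t: set() for t in web.taxa}
    for c, r in web.links:
        if c != r:
            prey[c].add(r)
    return prey


def _consumer_sets(web: FoodWeb) -> dict[str, set[str]]:
    cons: dict[str, set[str]] = {t: set() for t in web.taxa}
    for c, r in web.links:
        if c != r:
            cons[r].add(c)
    return cons


def connectance(web: FoodWeb) -> float:
    """Directed connectance L/S², self-loops (cannibalism) counted in L."""
    return web.n_links / web.n_species**2


def role_fractions(web: FoodWeb) -> tuple[float, float, float]:
    """(p_basal, p_intermediate, p_top).

    Basal: no resources; top: at least one resource and no consumers;
    intermediate: the rest.  Self-loops are ignored for both tests, so an
    isolated or purely cannibalistic taxon counts as basal.  The three
    fractions always sum to 1.
    """
    prey = _prey_sets(web)
    cons = _consumer_sets(web)
    S = web.n_species
    n_basal = sum(1 for t in web.taxa if not prey[t])
    n_top = sum(1 for t in web.taxa if prey[t] and not cons[t])
    return n_basal / S, (S - n_basal - n_top) / S, n_top / S


def trophic_levels(web: FoodWeb) -> TrophicPositions:
    """Solve the prey-averaged trophic-level system.

    Direct linear solve of (I - Q) TL = 1; if the matrix is
    ill-conditioned (condition estimate > 1e12) fall back to damped
    fixed-point iteration (damping 0.5, up to 10,000 sweeps).  A web whose
    consumers form a cycle with no feeding pathway down to a basal taxon
    has no finite solution; that raises :class:`TrophicLevelError` naming
    the offending strongly connected component.
    """
    taxa = list(web.taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    S = len(taxa)
    prey = _prey_sets(web)
    n = {t: len(prey[t]) for t in taxa}

    Q = np.zeros((S, S))
    for t in taxa:
        if n[t]:
            w = 1.0 / n[t]
            for p in prey[t]:
                Q[idx[t], idx[p]] = w
    A = np.eye(S) - Q
    b = np.ones(S)

    method: str = "linear_solve"
    tl = None
    try:
        if np.linalg.cond(A) <= 1e12:
            tl = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        tl = None

    if tl is None or not np.all(np.isfinite(tl)):
        method = "damped_iteration"
        tl = np.ones(S)
        converged = False
        for _ in range(10_000):
            new = 0.5 * tl + 0.5 * (b + Q @ tl)
            if np.max(np.abs(new - tl)) < 1e-12:
                tl = new
                converged = True
                break
            tl = new
        if not converged or np.max(np.abs(A @ tl - b)) > 1e-8:
            raise TrophicLevelError(_describe_bad_component(web, prey))

    resid = np.max(np.abs(A @ tl - b))
    if resid > 1e-8:
        raise TrophicLevelError(_describe_bad_component(web, prey))
    return TrophicPositions(
        web_id=web.web_id,
        TL={t: float(tl[idx[t]]) for t in taxa},
        n=n,
        method=method,  # type: ignore[arg-type]
        converged=True,
    )


def _describe_bad_component(web: FoodWeb, prey: dict[str, set[str]]) -> str:
    """Name a strongly connected consumer component with no basal pathway."""
    g = nx.DiGraph()
    g.add_nodes_from(web.taxa)
    for c, ps in prey.items():
        for p in ps:
            g.add_edge(c, p)  # points toward the resource (downward)
    basal = {t for t in web.taxa if not prey[t]}
    for scc in nx.strongly_connected_components(g):
        reachable = set(
            itertools.chain.from_iterable(nx.descendants(g, t) | {t} for t in scc)
        )
        if len(scc) > 1 and not (reachable & basal):
            members = ", ".join(sorted(scc))
            return (
                f"{web.web_id}: trophic levels undefined — strongly connected "
                f"component {{{members}}} has no feeding pathway to a basal taxon"
            )
    return f"{web.web_id}: trophic-level system did not converge"


def summarize_tl(pos: TrophicPositions) -> tuple[float, float]:
    """(max, arithmetic mean) of the trophic levels."""
    if not pos.converged:
        raise ValueError(f"{pos.web_id}: positions not converged")
    values = list(pos.TL.values())
    return max(values), sum(values) / len(values)


def omnivory_fraction(
    web: FoodWeb,
    pos: TrophicPositions,
    rule: Literal["integer", "range"] = "integer",
    tau: float = 0.5,
) -> float:
    """Fraction of taxa feeding on prey at multiple trophic levels.

    Default rule ("integer"): a taxon is an omnivore iff it has >= 2 prey
    (self excluded) whose trophic levels, rounded to the nearest integer,
    take >= 2 distinct values.  The alternative "range" rule calls any
    consumer whose prey span (max - min prey TL) exceeds ``tau`` an
    omnivore; it is stricter about what counts as "one level".
    """
    prey = _prey_sets(web)
    n_omni = 0
    for t in web.taxa:
        ps = prey[t]
        if len(ps) < 2:
            continue
        tls = [pos.TL[p] for p in ps]
        if rule == "integer":
            if len({round(x) for x in tls}) >= 2:
                n_omni += 1
        elif rule == "range":
            if max(tls) - min(tls) > tau:
                n_omni += 1
        else:
            raise ValueError(f"unknown omnivory rule {rule!r}")
    return n_omni / web.n_species


def metrics_row(
    web: FoodWeb,
    omnivory_rule: Literal["integer", "range"] = "integer",
    omnivory_tau: float = 0.5,
) -> MetricsRow:
    """Assemble the full descriptor vector for one web."""
    pos = trophic_levels(web)
    max_tl, mean_tl = summarize_tl(pos)
    p_b, p_i, p_t = role_fractions(web)
    return MetricsRow(
        web_id=web.web_id,
        S=web.n_species,
        L=web.n_links,
        C=connectance(web),
        p_basal=p_b,
        p_intermediate=p_i,
        p_top=p_t,
        omnivory=omnivory_fraction(web, pos, rule=omnivory_rule, tau=omnivory_tau),
        maxTL=max_tl,
        meanTL=mean_tl,
    )


METRIC_COLUMNS = (
    "S", "L", "C", "p_basal", "p_intermediate", "p_top",
    "omnivory", "maxTL", "meanTL",
)


def correlation_screen(
    rows: Sequence[MetricsRow], threshold: float = 0.7
) -> list[dict]:
    """Pairwise Pearson correlations among descriptor columns.

    Pairs with |r| >= ``threshold`` are flagged for analyst-driven
    exclusion; the pipeline's default variable set drops p_intermediate
    (collinear with p_basal) and meanTL (collinear with maxTL).  Pairs
    involving a constant column get r = nan and are never flagged.
    """
    if len(rows) < 3:
        raise ValueError("correlation screen needs at least 3 webs")
    data = {c: np.array([getattr(r, c) for r in rows], dtype=float)
            for c in METRIC_COLUMNS}
    out = []
    for a, b in itertools.combinations(METRIC_COLUMNS, 2):
        xa, xb = data[a], data[b]
        if np.std(xa) == 0 or np.std(xb) == 0:
            r = math.nan
        else:
            r = float(np.corrcoef(xa, xb)[0, 1])
        out.append(
            {
                "col_a": a,
                "col_b": b,
                "r": r,
                "flagged": bool(not math.isnan(r) and abs(r) >= threshold),
            }
        )
    return out
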