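"""Synthetic inputs with the statistical structure the analysis assumes.

Two layers:

* :func:`simulate_sem_data` draws rows from an exact linear-Gaussian path
  model — the "linear world" used for estimator validation (parameter
  recovery, chi-square calibration, model selection).
* :func:`generate_web_collection` builds a full synthetic study input —
  niche-model food webs whose size and connectance respond linearly to a
  temperature gradient, plus the covariate table — used to exercise the
  entire pipeline.  Only (S, C) are coupled to the covariates; basal
  fraction, omnivory and trophic level then emerge from the niche model
  rather than being imposed, as no generator can make all seven empirical
  descriptors obey an exact linear system simultaneously.

The niche model places each taxon at a uniform niche value and feeds it on
every taxon inside a contiguous diet interval whose width is beta-tuned to
hit a target connectance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .metrics import TrophicLevelError, trophic_levels
from .pathsem import PathModelSpec, _Layout
from .webio import FoodWeb, WebMetadata


class GenerationError(RuntimeError):
    pass


def niche_model_web(
    S: int, C_target: float, seed: int, max_attempts: int = 100
) -> FoodWeb:
    """Draw one niche-model food web with ``S`` taxa.

    Each taxon i gets a niche value n_i ~ U(0,1) and a feeding range
    r_i = x * n_i with x ~ Beta(1, (1-2C)/(2C)), centred at
    c_i ~ U(r_i/2, n_i); i consumes every j whose n_j lies inside the
    range.  The taxon with the smallest niche value gets range 0, so the
    web always has a basal taxon.  Draws are rejected until the web has at
    least one basal taxon, no isolated taxa, and a solvable prey-averaged
    trophic-level system (empirical webs in this class always do).
    """
    if S < 2:
        raise ValueError(f"need S >= 2, got {S}")
    if not 0.0 < C_target < 0.5:
        raise ValueError(f"need 0 < C_target < 0.5, got {C_target}")
    rng = np.random.default_rng(seed)
    beta_b = (1.0 - 2.0 * C_target) / (2.0 * C_target)
    labels = [f"t{i:03d}" for i in range(S)]

    for _ in range(max_attempts):
        nv = rng.uniform(0.0, 1.0, size=S)
        x = rng.beta(1.0, beta_b, size=S)
        r = x * nv
        r[np.argmin(nv)] = 0.0
        c = rng.uniform(r / 2.0, np.maximum(nv, r / 2.0 + 1e-12))
        lo, hi = c - r / 2.0, c + r / 2.0
        eats = (nv[None, :] >= lo[:, None]) & (nv[None, :] <= hi[:, None])
        eats &= r[:, None] > 0.0
        cons, res = np.nonzero(eats)
        links = frozenset(
            (labels[int(i)], labels[int(j)]) for i, j in zip(cons, res)
        )
        if not links:
            continue
        web = FoodWeb(web_id=f"niche_s{seed}", taxa=tuple(labels), links=links)
        prey = {t: set() for t in labels}
        consumers = {t: set() for t in labels}
        for a, b in links:
            prey[a].add(b)
            consumers[b].add(a)
        isolated = [t for t in labels if not prey[t] and not consumers[t]]
        basal = [t for t in labels if not (prey[t] - {t})]
        if isolated or not basal:
            continue
        try:
            trophic_levels(web)
        except TrophicLevelError:
            continue
        return web
    raise GenerationError(
        f"no valid niche web after {max_attempts} attempts "
        f"(S={S}, C_target={C_target}, seed={seed})"
    )


def theta_from_paths(
    spec: PathModelSpec,
    paths: dict[tuple[str, str], float],
    residual_var: dict[str, float] | float = 1.0,
    exog_cov: dict[tuple[str, str], float] | None = None,
    exog_var: float = 1.0,
) -> np.ndarray:
    """Assemble a flat parameter vector for ``spec``.

    ``paths`` maps (outcome, predictor) to a coefficient; omitted paths
    are 0.  ``residual_var`` is either one value for all endogenous
    variables or a per-outcome map.
    """
    layout = _Layout(spec)
    p = spec.p
    A = np.zeros((p, p))
    Psi = np.zeros((p, p))
    idx = layout.idx
    for (o, pr), coef in paths.items():
        if (idx[o], idx[pr]) not in layout.paths:
            raise ValueError(f"path {pr} -> {o} is not free in this model")
        A[idx[o], idx[pr]] = coef
    for o, _ in spec.equations:
        v = residual_var if isinstance(residual_var, (int, float)) else residual_var[o]
        if v <= 0:
            raise ValueError(f"residual variance for {o!r} must be > 0")
        Psi[idx[o], idx[o]] = v
    for v in spec.exogenous:
        Psi[idx[v], idx[v]] = exog_var
    for (a, b), cv in (exog_cov or {}).items():
        Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = cv
    return layout.pack(A, Psi)


def simulate_sem_data(
    spec: PathModelSpec, theta: np.ndarray, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` rows from the linear-Gaussian model (columns ordered as
    ``spec.variables``): exogenous block ~ MVN(0, Psi_exog), then each
    endogenous variable in topological order as its linear combination of
    parents plus a Normal residual."""
    rng = np.random.default_rng(seed)
    layout = _Layout(spec)
    A, Psi = layout.unpack(np.asarray(theta, dtype=float))
    p = spec.p
    X = np.zeros((n, p))
    if layout.exog:
        cov = Psi[np.ix_(layout.exog, layout.exog)]
        X[:, layout.exog] = rng.multivariate_normal(
            np.zeros(len(layout.exog)), cov, size=n, method="cholesky"
        )
    # equations are recursive; process outcomes in topological order
    order = _topological_outcomes(spec)
    idx = layout.idx
    for o in order:
        oi = idx[o]
        mean = X @ A[oi, :]
        X[:, oi] = mean + rng.normal(0.0, np.sqrt(Psi[oi, oi]), size=n)
    return X


def _topological_outcomes(spec: PathModelSpec) -> list[str]:
    preds = {o: set(pr) for o, pr in spec.equations}
    done = set(spec.exogenous)
    order: list[str] = []
    pending = dict(preds)
    while pending:
        ready = [o for o, ps in pending.items() if ps <= done]
        if not ready:  # unreachable: spec is validated acyclic
            raise RuntimeError("cyclic equations")
        for o in sorted(ready, key=list(pending).index):
            order.append(o)
            done.add(o)
            del pending[o]
    return order


def unit_variance_theta(
    spec: PathModelSpec,
    paths: dict[tuple[str, str], float],
    exog_cov: dict[tuple[str, str], float] | None = None,
) -> np.ndarray:
    """Parameter vector whose implied covariance has unit variances.

    Exogenous variances are 1 and each endogenous residual variance is
    1 minus the variance its parents explain, so the path coefficients
    are directly on the standardized (correlation) scale — the scale a
    fit to z-scored data estimates.  Raises if any equation would need a
    non-positive residual variance.
    """
    layout = _Layout(spec)
    idx = layout.idx
    p = spec.p
    Sigma = np.zeros((p, p))
    for v in spec.exogenous:
        Sigma[idx[v], idx[v]] = 1.0
    for (a, b), cv in (exog_cov or {}).items():
        Sigma[idx[a], idx[b]] = Sigma[idx[b], idx[a]] = cv
    coef = {(o, pr): 0.0 for o, prs in spec.equations for pr in prs}
    for key, val in paths.items():
        if key not in coef:
            raise ValueError(f"path {key[1]} -> {key[0]} is not free in this model")
        coef[key] = val
    resid: dict[str, float] = {}
    done = list(spec.exogenous)
    for o in _topological_outcomes(spec):
        preds = dict(spec.equations)[o]
        P = [idx[pr] for pr in preds]
        b = np.array([coef[(o, pr)] for pr in preds])
        explained = float(b @ Sigma[np.ix_(P, P)] @ b) if P else 0.0
        rv = 1.0 - explained
        if rv <= 0:
            raise ValueError(
                f"paths into {o!r} explain variance {explained:.3f} >= 1"
            )
        resid[o] = rv
        oi = idx[o]
        for t in done:
            ti = idx[t]
            Sigma[oi, ti] = Sigma[ti, oi] = float(b @ Sigma[P, ti]) if P else 0.0
        Sigma[oi, oi] = 1.0
        done.append(o)
    return theta_from_paths(spec, paths, residual_var=resid, exog_cov=exog_cov)


# Ground-truth standardized coefficients of the temperature-only world:
# latitude drives temperature (the global gradient) but touches web
# structure only through it.  Signs follow the causal story the analysis
# is built to detect: warming thins species, basal fraction and links
# directly, and feeds omnivory/connectance/trophic level indirectly.
TEMPERATURE_WORLD_PATHS: dict[tuple[str, str], float] = {
    ("temperature", "latitude"): -0.8,
    ("S", "temperature"): -0.5,
    ("p_basal", "temperature"): -0.5,
    ("L", "temperature"): -0.3,
    ("omnivory", "temperature"): 0.3,
    ("L", "aquatic"): 0.3,
    ("p_basal", "S"): -0.3,
    ("p_top", "p_basal"): -0.3,
    ("L", "S"): 0.5,
    ("omnivory", "p_basal"): -0.5,
    ("omnivory", "L"): 0.3,
    ("C", "S"): -0.5,
    ("C", "L"): 0.5,
    ("C", "p_basal"): -0.3,
    ("maxTL", "C"): 0.5,
    ("maxTL", "p_basal"): -0.3,
}


def simulate_study_matrix(n: int, seed: int) -> "pd.DataFrame":
    """Draw an exact linear-Gaussian analysis matrix (all ten study
    columns) under the temperature-only ground truth
    :data:`TEMPERATURE_WORLD_PATHS`.  The aquatic indicator is Gaussian
    here — this is the estimator-validation world, not the web
    generator."""
    from .study import candidate_model  # deferred: study imports pathsem only

    spec = candidate_model("both").spec
    theta = unit_variance_theta(spec, TEMPERATURE_WORLD_PATHS)
    X = simulate_sem_data(spec, theta, n, seed)
    import pandas as pd

    return pd.DataFrame(X, columns=list(spec.variables))


@dataclass(frozen=True)
class GenerativeConfig:
    """Study-scale defaults for the synthetic 65-web collection.

    The collection mirrors the empirical compilation's scale: 65 webs
    averaging ~64 species and ~427 links (mean connectance ~0.105).
    Latitude is drawn on [0, 70] degrees (read as absolute latitude);
    mean annual temperature falls linearly with latitude at 0.42 degC per
    degree from a 27 degC equatorial intercept, with 3 degC of scatter —
    the familiar global gradient.  Warmer webs are smaller and slightly
    more connected (species decline, connectance rise with temperature),
    the qualitative structure the analysis is designed to detect.
    """

    n_webs: int = 65
    seed: int = 0
    lat_range: tuple[float, float] = (0.0, 70.0)
    temp_intercept: float = 27.0
    temp_slope: float = 0.42       # degC lost per degree latitude
    temp_noise_sd: float = 3.0
    aquatic_prob: float = 0.7
    S_base: float = 64.0
    S_per_sd_temp: float = -10.0   # species change per SD of temperature
    S_floor: int = 25
    C_base: float = 0.105
    C_per_sd_temp: float = 0.012
    C_bounds: tuple[float, float] = (0.03, 0.45)

    def __post_init__(self) -> None:
        if self.temp_noise_sd <= 0:
            raise ValueError("temp_noise_sd must be > 0")
        if not 0.02 < self.C_base < 0.5:
            raise ValueError("C_base must lie in (0.02, 0.5)")
        if self.S_base < 2:
            raise ValueError("S_base must be >= 2")


_AQUATIC_CLASSES = ("freshwater", "marine", "estuarine")


def generate_web_collection(
    config: GenerativeConfig | None = None,
) -> tuple[list[FoodWeb], list[WebMetadata], dict]:
    """Generate a full synthetic study input.

    Returns the webs, their covariate records, and a ground-truth record
    (the config plus each web's latitude/temperature and target S and C)
    for recovery and sign-structure tests.
    """
    cfg = config or GenerativeConfig()
    rng = np.random.default_rng(cfg.seed)
    lat = rng.uniform(*cfg.lat_range, size=cfg.n_webs)
    temp = (
        cfg.temp_intercept
        - cfg.temp_slope * lat
        + rng.normal(0.0, cfg.temp_noise_sd, size=cfg.n_webs)
    )
    aquatic = rng.random(cfg.n_webs) < cfg.aquatic_prob
    lon = rng.uniform(-180.0, 180.0, size=cfg.n_webs)
    z_temp = (temp - temp.mean()) / temp.std(ddof=1)
    target_S = np.maximum(
        np.rint(cfg.S_base + cfg.S_per_sd_temp * z_temp).astype(int), cfg.S_floor
    )
    target_C = np.clip(cfg.C_base + cfg.C_per_sd_temp * z_temp, *cfg.C_bounds)

    webs: list[FoodWeb] = []
    meta: list[WebMetadata] = []
    per_web = []
    for i in range(cfg.n_webs):
        web_seed = int(rng.integers(0, 2**31 - 1))
        web = niche_model_web(int(target_S[i]), float(target_C[i]), seed=web_seed)
        web_id = f"syn{i:03d}"
        web = FoodWeb(web_id=web_id, taxa=web.taxa, links=web.links)
        eco = (
            _AQUATIC_CLASSES[int(rng.integers(0, len(_AQUATIC_CLASSES)))]
            if aquatic[i]
            else "terrestrial"
        )
        meta.append(
            WebMetadata(
                web_id=web_id,
                latitude=float(lat[i]),
                longitude=float(lon[i]),
                temperature_C=float(temp[i]),
                ecosystem=eco,
            )
        )
        webs.append(web)
        per_web.append(
            {
                "web_id": web_id,
                "latitude": float(lat[i]),
                "temperature_C": float(temp[i]),
                "aquatic": int(aquatic[i]),
                "target_S": int(target_S[i]),
                "target_C": float(target_C[i]),
                "niche_seed": web_seed,
            }
        )
    truth = {"config": asdict(cfg), "webs": per_web}
    return webs, meta, truth
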