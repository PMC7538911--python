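"""Hierarchical Bayesian regression of Likert ratings on face exaggeration.

The observation model is a Gaussian linear mixed model on the 1-9 ratings:

    rating_i = x_i' b + z_i' u_participant(i) + w_i' u_face(i) + e_i,

with fixed effects for the exaggeration level (linear, optionally
quadratic), face sex, rater sex and their interactions with the level
terms; maximal random structure (by-participant and by-face intercepts and
slopes for every fixed term that varies within the grouping); and
e_i ~ N(0, sigma^2).  Face grouping is by *source* face, so the seven
exaggerated versions of one face share its random effects.

Inference is a blocked Gibbs sampler with exact conjugate conditionals:
fixed effects get a normal(0, 5^2) prior; the residual scale a
half-t(3, 2.5) prior and the random-effect covariance matrices the
Huang-Wand (2013) inverse-Wishart scale mixture (marginal half-t(2, 2.5)
standard deviations, near-uniform correlations).  Candidate models are
ranked by WAIC computed from retained pointwise log-likelihood draws.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ModelFitError, SpecificationError
from .face_space import base_face_id
from .trait_model import RATING_MAX, RATING_MIN

# prior hyperparameters (see docs/methods.md)
BETA_PRIOR_SD = 5.0
LAMBDA_PRIOR_SD = 1.0  # prior SD of the redundant scale multipliers
RE_SWEEPS = 2  # random-effect block sweeps per Gibbs iteration
HW_NU_COV = 2.0  # Huang-Wand nu for covariance matrices
SIGMA_NU = 3.0  # half-t df for the residual scale
SCALE_A = 2.5  # half-t scale for all standard deviations

LEVEL_TERMS = ("level", "level2")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; the defaults are the full study-scale settings."""

    iterations: int = 13_000
    burn_in: int = 3_000
    chains: int = 4
    seed: int = 1

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise SpecificationError("burn_in must be smaller than iterations")


#: reduced settings for desk-scale runs and tests
TEST_SCALE_MCMC = MCMCConfig(iterations=2_000, burn_in=500, chains=2, seed=1)


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed terms enter the regression.

    The quadratic term is only allowed together with the linear term, and
    the sex factors always bring their interactions with whatever level
    terms are present.
    """

    level: bool = True
    quadratic: bool = True
    face_sex: bool = True
    rater_sex: bool = True

    def __post_init__(self):
        if self.quadratic and not self.level:
            raise SpecificationError(
                "quadratic level term requires the linear level term"
            )

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        terms = ["intercept"]
        lv = ["level"] if self.level else []
        if self.quadratic:
            lv.append("level2")
        terms += lv
        for factor in ("face_sex", "rater_sex"):
            if getattr(self, factor):
                terms.append(factor)
                terms += [f"{factor}:{t}" for t in lv]
        return tuple(terms)

    @property
    def name(self) -> str:
        parts = []
        if self.level:
            parts.append("level")
        if self.quadratic:
            parts.append("quad")
        if self.face_sex:
            parts.append("face_sex")
        if self.rater_sex:
            parts.append("rater_sex")
        return "+".join(parts) if parts else "intercept_only"


def candidate_specs(include_bare_level: bool = True) -> list[ModelSpec]:
    """The lattice of candidate models: linear level term always present,
    optionally the quadratic term, face sex (with interactions) and rater
    sex (with interactions)."""
    out = []
    for quad, fs, rs in itertools.product([False, True], repeat=3):
        out.append(ModelSpec(level=True, quadratic=quad, face_sex=fs, rater_sex=rs))
    if not include_bare_level:
        out = [s for s in out if s.quadratic or s.face_sex or s.rater_sex]
    return out


def validate_trial_data(df: pd.DataFrame) -> None:
    required = {"participant_id", "rater_sex", "face_id", "face_sex", "level_sd", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise SpecificationError(f"trial data missing columns {sorted(missing)}")
    r = df["rating"].to_numpy()
    if r.min() < RATING_MIN or r.max() > RATING_MAX:
        raise SpecificationError("ratings outside the 1-9 scale")
    if not np.all(np.isfinite(df["level_sd"].to_numpy(float))):
        raise SpecificationError("non-finite exaggeration level")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _sex_code(values: pd.Series) -> np.ndarray:
    # centred +/-0.5 coding: male = +0.5, female = -0.5
    return np.where(values.to_numpy() == "male", 0.5, -0.5)


def _term_columns(df: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    n = len(df)
    level = df["level_sd"].to_numpy(float)
    base = {
        "intercept": np.ones(n),
        "level": level,
        "level2": level**2,
        "face_sex": _sex_code(df["face_sex"]),
        "rater_sex": _sex_code(df["rater_sex"]),
    }

    def col(term: str) -> np.ndarray:
        parts = term.split(":")
        out = base[parts[0]].copy()
        for p in parts[1:]:
            out *= base[p]
        return out

    return np.column_stack([col(t) for t in terms])


@dataclass
class _Group:
    label: str
    codes: np.ndarray  # (n,) unit index per observation
    n_units: int
    terms: tuple[str, ...]
    Z: np.ndarray  # (n, q)
    ZtZ: np.ndarray  # (n_units, q, q)
    # interweaving moves: (fixed index, random-term index, per-unit constant)
    shifts: list[tuple[int, int, np.ndarray]] = field(default_factory=list)


def _varies_within(col: np.ndarray, codes: np.ndarray, n_units: int) -> bool:
    order = np.argsort(codes, kind="stable")
    c, g = col[order], codes[order]
    bounds = np.searchsorted(g, np.arange(n_units + 1))
    for j in range(n_units):
        seg = c[bounds[j] : bounds[j + 1]]
        if seg.size > 1 and np.ptp(seg) > 0:
            return True
    return False


def _build_group(
    df: pd.DataFrame,
    label: str,
    ids: pd.Series,
    fixed_terms: tuple[str, ...],
    requested: tuple[str, ...] | None,
) -> _Group:
    codes, units = pd.factorize(ids)
    n_units = len(units)
    candidates = requested if requested is not None else fixed_terms
    terms: list[str] = []
    for t in candidates:
        if t == "intercept":
            terms.append(t)
            continue
        col = _term_columns(df, (t,))[:, 0]
        if _varies_within(col, codes, n_units):
            terms.append(t)
        elif requested is not None:
            raise SpecificationError(
                f"random slope for {t!r} requested by-{label}, but {t} takes a "
                f"single value within every {label}"
            )
    if "intercept" not in terms:
        terms.insert(0, "intercept")
    Z = _term_columns(df, tuple(terms))
    q = Z.shape[1]
    ZtZ = np.zeros((n_units, q, q))
    np.add.at(ZtZ, codes, Z[:, :, None] * Z[:, None, :])
    group = _Group(label, codes, n_units, tuple(terms), Z, ZtZ)
    group.shifts = _shift_moves(df, fixed_terms, group)
    return group


def _shift_moves(
    df: pd.DataFrame, fixed_terms: tuple[str, ...], g: _Group
) -> list[tuple[int, int, np.ndarray]]:
    """Fixed-effect / random-effect pairs related by a group-constant factor.

    A fixed column f whose within-group-varying part equals a random-term
    column t (up to a per-group constant c) defines an exact location
    reparameterization u_t += delta*c, beta_f -= delta that leaves the
    likelihood invariant; Gibbs-sampling delta from its conjugate
    conditional (an ancillarity-sufficiency interweaving move) breaks the
    posterior coupling that otherwise mixes slowly.
    """
    moves = []
    first = np.full(g.n_units, -1, dtype=int)
    for i, c in enumerate(g.codes):
        if first[c] < 0:
            first[c] = i
    for fi, f in enumerate(fixed_terms):
        factors = [] if f == "intercept" else f.split(":")
        varying, constant = [], []
        for fac in factors:
            col = _term_columns(df, (fac,))[:, 0]
            if _varies_within(col, g.codes, g.n_units):
                varying.append(fac)
            else:
                constant.append(fac)
        t_name = ":".join(varying) if varying else "intercept"
        if t_name not in g.terms:
            continue
        ti = g.terms.index(t_name)
        if constant:
            c_col = _term_columns(df, (":".join(constant),))[:, 0]
            c_unit = c_col[first]
        else:
            c_unit = np.ones(g.n_units)
        moves.append((fi, ti, c_unit))
    return moves


# ---------------------------------------------------------------------------
# posterior containers
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Per-parameter EAP / 95% CrI / Rhat plus retained draws."""

    table: pd.DataFrame  # index: parameter; columns: eap, cri_low, cri_high, rhat
    draws: dict[str, np.ndarray]  # name -> (chains, kept)
    log_lik: np.ndarray | None  # (chains, kept_ll, n_obs) or None
    spec: ModelSpec | None
    mcmc: MCMCConfig
    n_obs: int
    random_structure: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def eap(self, name: str) -> float:
        return float(self.table.loc[name, "eap"])

    def cri(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["cri_low"]), float(row["cri_high"])

    def max_rhat(self) -> float:
        return float(np.nanmax(self.table["rhat"].to_numpy()))


@dataclass
class ModelComparison:
    """WAIC ladder over candidate models, sorted ascending (best first)."""

    ladder: pd.DataFrame  # columns: model, waic, p_waic; sorted by waic
    fits: dict[str, PosteriorSummary]

    @property
    def best(self) -> str:
        return str(self.ladder.iloc[0]["model"])

    @property
    def best_fit(self) -> PosteriorSummary:
        return self.fits[self.best]


def _split_rhat(x: np.ndarray) -> float:
    """Split-Rhat (potential scale reduction) over (chains, draws) draws."""
    import arviz as az

    if x.shape[0] * x.shape[1] < 4 or np.ptp(x) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(x))


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------

def _run_chain(
    y: np.ndarray,
    X: np.ndarray,
    groups: list[_Group],
    n_keep: int,
    burn_in: int,
    rng: np.random.Generator,
    loglik_stride: int,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """One Gibbs chain.

    Random effects use the redundant multiplicative parameterization
    u_j = Lambda xi_j with Lambda = diag(lambda), xi_j ~ N(0, Psi): the
    scale multipliers lambda enter the mean linearly and get a conjugate
    Gaussian update, which lets near-zero variance components mix through
    zero instead of sticking at the boundary.  The implied covariance is
    Sigma = Lambda Psi Lambda.  Location interweaving moves (``shifts``)
    decorrelate fixed effects from group means.
    """
    n, p = X.shape
    XtX = X.T @ X
    prior_prec_b = np.eye(p) / BETA_PRIOR_SD**2

    # state
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    sigma2 = max(float(np.var(y - X @ beta)), 1e-3)
    a_sigma = 1.0
    Xi = [np.zeros((g.n_units, len(g.terms))) for g in groups]
    lam = [np.full(len(g.terms), 0.5) for g in groups]
    Psi = [np.eye(len(g.terms)) for g in groups]
    Psi_inv = [np.linalg.inv(P) for P in Psi]
    a_g = [np.ones(len(g.terms)) for g in groups]

    def contrib(k: int) -> np.ndarray:
        g = groups[k]
        return np.einsum("nq,nq->n", g.Z, (Xi[k] * lam[k])[g.codes])

    # storage
    out_beta = np.empty((n_keep, p))
    out_sd = [np.empty((n_keep, len(g.terms))) for g in groups]
    n_cor = [len(g.terms) * (len(g.terms) - 1) // 2 for g in groups]
    out_cor = [np.empty((n_keep, c)) for c in n_cor]
    out_sigma = np.empty(n_keep)
    kept_ll = int(np.ceil(n_keep / loglik_stride))
    out_ll = np.empty((kept_ll, n))

    total = burn_in + n_keep
    tril = [np.tril_indices(len(g.terms), k=-1) for g in groups]
    for it in range(total):
        contribs = [contrib(k) for k in range(len(groups))]

        # fixed effects
        r = y - sum(contribs) if groups else y.copy()
        A = XtX / sigma2 + prior_prec_b
        b = X.T @ r / sigma2
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

        fitted_fixed = X @ beta
        for k, g in enumerate(groups):
            q = len(g.terms)
            for _sweep in range(RE_SWEEPS):
                other = sum(contribs[j] for j in range(len(groups)) if j != k)
                r = y - fitted_fixed - other

                # raw effects xi_j | rest (conjugate normal, batched over units)
                rhs = np.empty((g.n_units, q))
                for t in range(q):
                    rhs[:, t] = np.bincount(
                        g.codes, weights=g.Z[:, t] * r, minlength=g.n_units
                    )
                rhs *= lam[k][None, :] / sigma2
                A = (np.outer(lam[k], lam[k]) * g.ZtZ) / sigma2 + Psi_inv[k][None, :, :]
                mean = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
                Lg = np.linalg.cholesky(A)
                z = rng.standard_normal((g.n_units, q, 1))
                Xi[k] = mean + np.linalg.solve(np.transpose(Lg, (0, 2, 1)), z)[:, :, 0]

                # scale multipliers lambda | rest (linear in the mean, conjugate)
                C = g.Z * Xi[k][g.codes]
                A = C.T @ C / sigma2 + np.eye(q) / LAMBDA_PRIOR_SD**2
                b = C.T @ r / sigma2
                Lq = np.linalg.cholesky(A)
                lam[k] = np.linalg.solve(A, b) + np.linalg.solve(
                    Lq.T, rng.standard_normal(q)
                )

                # interweaving location moves between beta and this group's
                # effective random effects u = lambda * xi (see _shift_moves)
                U = Xi[k] * lam[k][None, :]
                Sigma = np.outer(lam[k], lam[k]) * Psi[k]
                P = np.linalg.inv(Sigma)
                for fi, ti, c in g.shifts:
                    if abs(lam[k][ti]) < 1e-12:
                        continue
                    prec = P[ti, ti] * float(c @ c) + 1.0 / BETA_PRIOR_SD**2
                    lin = beta[fi] / BETA_PRIOR_SD**2 - float((U @ P[ti]) @ c)
                    delta = lin / prec + rng.standard_normal() / np.sqrt(prec)
                    U[:, ti] += delta * c
                    Xi[k][:, ti] = U[:, ti] / lam[k][ti]
                    beta[fi] -= delta
                fitted_fixed = X @ beta
                contribs[k] = contrib(k)

                # covariance of the raw effects (Huang-Wand inverse-Wishart mixture)
                S = Xi[k].T @ Xi[k]
                df = HW_NU_COV + q - 1 + g.n_units
                scale = 2.0 * HW_NU_COV * np.diag(1.0 / a_g[k]) + S
                Psi[k] = np.atleast_2d(
                    stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
                )
                Psi_inv[k] = np.linalg.inv(Psi[k])
                rate_a = HW_NU_COV * np.diag(Psi_inv[k]) + 1.0 / SCALE_A**2
                a_g[k] = 1.0 / rng.gamma((HW_NU_COV + q) / 2.0, 1.0 / rate_a)

        # residual scale (half-t via inverse-gamma mixture)
        resid = y - fitted_fixed - (sum(contribs) if groups else 0.0)
        ssr = float(resid @ resid)
        sigma2 = 1.0 / rng.gamma((SIGMA_NU + n) / 2.0, 1.0 / (SIGMA_NU / a_sigma + ssr / 2.0))
        a_sigma = 1.0 / rng.gamma(
            (SIGMA_NU + 1) / 2.0, 1.0 / (SIGMA_NU / sigma2 + 1.0 / SCALE_A**2)
        )

        j = it - burn_in
        if j >= 0:
            out_beta[j] = beta
            out_sigma[j] = np.sqrt(sigma2)
            for k, g in enumerate(groups):
                Sigma = np.outer(lam[k], lam[k]) * Psi[k]
                sd = np.sqrt(np.diag(Sigma))
                out_sd[k][j] = sd
                if n_cor[k]:
                    with np.errstate(invalid="ignore"):
                        Cm = Sigma / np.outer(sd, sd)
                    out_cor[k][j] = np.nan_to_num(Cm[tril[k]])
            if j % loglik_stride == 0:
                out_ll[j // loglik_stride] = (
                    -0.5 * np.log(2 * np.pi * sigma2) - resid**2 / (2 * sigma2)
                )

    return (
        {
            "beta": out_beta,
            "sd": out_sd,
            "cor": out_cor,
            "sigma": out_sigma,
        },
        out_ll,
    )


def fit_hierarchical(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
    random_terms: dict[str, tuple[str, ...]] | None = None,
    store_loglik: bool = True,
    max_loglik_draws: int = 1_000,
    rhat_warn: float = 1.01,
) -> PosteriorSummary:
    """Fit the hierarchical rating regression by blocked Gibbs sampling.

    ``data`` is long-format trial data (one row per rating event); faces
    are grouped by source face id.  ``random_terms`` optionally pins the
    random structure per grouping ("participant", "face"); by default every
    fixed term that varies within a grouping receives a random slope (the
    maximal structure justified by the data).  Warns when any split-Rhat
    exceeds ``rhat_warn``.
    """
    spec = spec if spec is not None else ModelSpec()
    mcmc = mcmc if mcmc is not None else MCMCConfig()
    validate_trial_data(data)
    df = data.reset_index(drop=True)
    if df["participant_id"].nunique() < 2:
        raise SpecificationError("need at least 2 participants")
    base_ids = df["face_id"].map(base_face_id)
    if base_ids.nunique() < 2:
        raise SpecificationError("need at least 2 (source) faces")
    if df["level_sd"].nunique() < 2 and spec.level:
        raise SpecificationError("need at least 2 distinct exaggeration levels")

    y = df["rating"].to_numpy(float)
    terms = spec.fixed_terms
    X = _term_columns(df, terms)
    groups = [
        _build_group(
            df, "participant", df["participant_id"], terms,
            None if random_terms is None else tuple(random_terms.get("participant", ())) or None,
        ),
        _build_group(
            df, "face", base_ids, terms,
            None if random_terms is None else tuple(random_terms.get("face", ())) or None,
        ),
    ]

    n_keep = mcmc.iterations - mcmc.burn_in
    stride = max(1, int(np.ceil(n_keep / max_loglik_draws))) if store_loglik else n_keep
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chain_draws, chain_ll = [], []
    for seq in seeds:
        d, ll = _run_chain(
            y, X, groups, n_keep, mcmc.burn_in, np.random.default_rng(seq), stride
        )
        chain_draws.append(d)
        chain_ll.append(ll)

    draws: dict[str, np.ndarray] = {}
    for i, t in enumerate(terms):
        draws[f"b_{t}"] = np.stack([d["beta"][:, i] for d in chain_draws])
    for k, g in enumerate(groups):
        for i, t in enumerate(g.terms):
            draws[f"sd_{g.label}_{t}"] = np.stack(
                [d["sd"][k][:, i] for d in chain_draws]
            )
        idx = np.tril_indices(len(g.terms), k=-1)
        for c, (i, j) in enumerate(zip(*idx)):
            draws[f"cor_{g.label}_{g.terms[i]}.{g.terms[j]}"] = np.stack(
                [d["cor"][k][:, c] for d in chain_draws]
            )
    draws["sigma"] = np.stack([d["sigma"] for d in chain_draws])

    rows = []
    for name, x in draws.items():
        pooled = x.reshape(-1)
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "eap": pooled.mean(),
                "cri_low": lo,
                "cri_high": hi,
                "rhat": _split_rhat(x),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    worst = np.nanmax(table["rhat"].to_numpy()) if len(table) else np.nan
    if np.isfinite(worst) and worst > rhat_warn:
        bad = table.index[table["rhat"] > rhat_warn].tolist()
        warnings.warn(
            f"Rhat > {rhat_warn} for {bad[:5]} (max {worst:.3f}); "
            "consider more iterations",
            stacklevel=2,
        )

    return PosteriorSummary(
        table=table,
        draws=draws,
        log_lik=np.stack(chain_ll) if store_loglik else None,
        spec=spec,
        mcmc=mcmc,
        n_obs=len(df),
        random_structure={g.label: g.terms for g in groups},
    )


# ---------------------------------------------------------------------------
# WAIC and model selection
# ---------------------------------------------------------------------------

def waic_detail(fit: PosteriorSummary | np.ndarray) -> tuple[float, float, float]:
    """(WAIC, lppd, p_waic) from pointwise log-likelihood draws.

    lppd = sum_i log mean_s exp(ll_is); p_waic = sum_i var_s(ll_is);
    WAIC = -2 (lppd - p_waic).  Accepts a fit with retained log-likelihood
    or a raw (draws, n_obs) table.
    """
    if isinstance(fit, PosteriorSummary):
        if fit.log_lik is None:
            raise ContractError("fit has no retained pointwise log-likelihood")
        ll = fit.log_lik.reshape(-1, fit.log_lik.shape[-1])
    else:
        ll = np.asarray(fit, float)
        if ll.ndim != 2:
            raise ContractError("log-likelihood table must be (draws, n_obs)")
    s = ll.shape[0]
    from scipy.special import logsumexp

    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), lppd, p_waic


def waic(fit: PosteriorSummary | np.ndarray) -> float:
    """Widely applicable information criterion, -2(lppd - p_waic)."""
    return waic_detail(fit)[0]


def select_best(
    data: pd.DataFrame,
    candidates: list[ModelSpec] | None = None,
    mcmc: MCMCConfig | None = None,
    **fit_kwargs,
) -> ModelComparison:
    """Fit every candidate, rank by WAIC ascending, tag the minimum as best."""
    candidates = candidates if candidates is not None else candidate_specs()
    if len(candidates) < 2:
        raise SpecificationError("model selection needs at least 2 candidates")
    rows, fits = [], {}
    for k, spec in enumerate(candidates):
        try:
            cfg = mcmc if mcmc is None else replace(mcmc, seed=mcmc.seed + 1000 * k)
            fit = fit_hierarchical(data, spec, cfg, store_loglik=True, **fit_kwargs)
            w, _, p_eff = waic_detail(fit)
        except Exception as exc:  # noqa: BLE001 - report the failing candidate
            raise ModelFitError(spec.name, str(exc)) from exc
        rows.append({"model": spec.name, "waic": w, "p_waic": p_eff})
        fits[spec.name] = fit
    ladder = (
        pd.DataFrame(rows).sort_values("waic", kind="stable").reset_index(drop=True)
    )
    return ModelComparison(ladder=ladder, fits=fits)


def generated_quantities(
    fit_a: PosteriorSummary, fit_b: PosteriorSummary, term: str
) -> PosteriorSummary:
    """Draw-wise difference posterior ``term_a - term_b`` between two fits."""
    for label, fit in (("a", fit_a), ("b", fit_b)):
        if term not in fit.draws:
            raise ContractError(f"term {term!r} absent from fit {label}")
    a, b = fit_a.draws[term], fit_b.draws[term]
    chains = min(a.shape[0], b.shape[0])
    kept = min(a.shape[1], b.shape[1])
    delta = a[:chains, :kept] - b[:chains, :kept]
    pooled = delta.reshape(-1)
    lo, hi = np.percentile(pooled, [2.5, 97.5])
    name = f"delta_{term}"
    table = pd.DataFrame(
        [
            {
                "parameter": name,
                "eap": pooled.mean(),
                "cri_low": lo,
                "cri_high": hi,
                "rhat": _split_rhat(delta),
            }
        ]
    ).set_index("parameter")
    return PosteriorSummary(
        table=table,
        draws={name: delta},
        log_lik=None,
        spec=None,
        mcmc=fit_a.mcmc,
        n_obs=fit_a.n_obs,
    )
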