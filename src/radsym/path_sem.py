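"""Observed-variable path analysis with Satorra-Bentler robust statistics.

A :class:`PathModel` is a recursive (acyclic) system of linear equations
among measured variables: directed edges carry free regression
coefficients, exogenous variables get free variances and covariances,
endogenous variables get residual variances (optionally residual
covariances between named pairs).  ``fit()`` minimises the normal-theory
maximum-likelihood discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

with Sigma(theta) = (I-B)^-1 Psi (I-B)^-T, and returns a
:class:`SEMResults` carrying T_ML = (n-1) F_ML, the Satorra-Bentler
scaled statistic T_SB = T_ML / c (c from empirical fourth-order
moments), normal-theory and sandwich standard errors, CFI against the
independence baseline, AIC = T_ML + 2q, and standardized coefficients.

Model acceptance follows the usual path-analysis convention used here:
p(T_SB) > 0.05 and CFI > 0.95; redundant paths are pruned backward by
AIC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "PathModel",
    "SEMResults",
    "prepare_covariates",
    "prune_model",
]


# --------------------------------------------------------------- helpers
def _vech_indices(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1)]


def vech(M: np.ndarray) -> np.ndarray:
    p = M.shape[0]
    return np.array([M[i, j] for i, j in _vech_indices(p)])


def duplication_matrix(p: int) -> np.ndarray:
    """D with vec(M) = D vech(M) for symmetric M."""
    idx = _vech_indices(p)
    D = np.zeros((p * p, len(idx)))
    for k, (i, j) in enumerate(idx):
        D[i * p + j, k] = 1.0
        D[j * p + i, k] = 1.0
    return D


class SEMConvergenceError(RuntimeError):
    def __init__(self, msg: str, best_x=None, grad_norm=None):
        super().__init__(msg)
        self.best_x = best_x
        self.grad_norm = grad_norm


# ------------------------------------------------------------ the model
@dataclass
class PathModel:
    """A recursive path model over observed variables.

    Parameters
    ----------
    variables : list of str
        Ordered variable names (defines matrix order).
    edges : list of (cause, effect)
        Directed paths, each with a free coefficient.
    resid_covs : list of (a, b)
        Endogenous pairs given a free residual covariance (e.g. two
        symbionts influenced by common unmeasured factors).
    exog_cov : bool
        Free covariances among exogenous variables (default).  With
        ``False`` only their variances are free — an empty edge list
        then gives the independence model.
    """

    variables: list[str]
    edges: list[tuple[str, str]]
    resid_covs: list[tuple[str, str]] = field(default_factory=list)
    exog_cov: bool = True

    def __post_init__(self) -> None:
        for c, e in self.edges:
            if c not in self.variables or e not in self.variables:
                raise ValueError(f"edge ({c}->{e}) uses unknown variable")
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge graph has a cycle; only recursive models")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")

    # -- structure -----------------------------------------------------
    @property
    def endogenous(self) -> list[str]:
        targets = {e for _, e in self.edges}
        return [v for v in self.variables if v in targets]

    @property
    def exogenous(self) -> list[str]:
        targets = {e for _, e in self.edges}
        return [v for v in self.variables if v not in targets]

    @property
    def param_names(self) -> list[str]:
        names = [f"{c}->{e}" for c, e in self.edges]
        ex = self.exogenous
        if self.exog_cov:
            for i, a in enumerate(ex):
                for b in ex[: i + 1]:
                    names.append(f"{b}~~{a}" if a != b else f"var({a})")
        else:
            names += [f"var({a})" for a in ex]
        names += [f"resid({v})" for v in self.endogenous]
        names += [f"rcov({a},{b})" for a, b in self.resid_covs]
        return names

    @property
    def n_params(self) -> int:
        ne = len(self.exogenous)
        nex = ne * (ne + 1) // 2 if self.exog_cov else ne
        return (len(self.edges) + nex
                + len(self.endogenous) + len(self.resid_covs))

    @property
    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_params

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]],
        variables: list[str] | None = None,
        resid_covs: list[tuple[str, str]] | None = None,
    ) -> "PathModel":
        if variables is None:
            variables = []
            for c, e in edges:
                for v in (c, e):
                    if v not in variables:
                        variables.append(v)
        return cls(variables=variables, edges=list(edges),
                   resid_covs=list(resid_covs or []))

    @classmethod
    def from_spec(cls, text: str) -> "PathModel":
        """Parse a plain-text edge list: ``cause -> effect`` per line,
        ``a ~~ b`` for residual covariances, ``#`` comments."""
        edges, rcovs = [], []
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "->" in line:
                c, e = (s.strip() for s in line.split("->"))
                edges.append((c, e))
            elif "~~" in line:
                a, b = (s.strip() for s in line.split("~~"))
                rcovs.append((a, b))
            else:
                raise ValueError(f"cannot parse model line: {line!r}")
        return cls.from_edges(edges, resid_covs=rcovs)

    def drop_edge(self, edge: tuple[str, str]) -> "PathModel":
        edges = [e for e in self.edges if e != edge]
        return PathModel(variables=list(self.variables), edges=edges,
                         resid_covs=list(self.resid_covs),
                         exog_cov=self.exog_cov)

    # -- parameter plumbing --------------------------------------------
    def _unpack(self, theta: np.ndarray):
        p = len(self.variables)
        pos = {v: i for i, v in enumerate(self.variables)}
        B = np.zeros((p, p))
        k = 0
        for c, e in self.edges:
            B[pos[e], pos[c]] = theta[k]
            k += 1
        Psi = np.zeros((p, p))
        ex = self.exogenous
        if self.exog_cov:
            for i, a in enumerate(ex):
                for b in ex[: i + 1]:
                    Psi[pos[a], pos[b]] = Psi[pos[b], pos[a]] = theta[k]
                    k += 1
        else:
            for a in ex:
                Psi[pos[a], pos[a]] = theta[k]
                k += 1
        for v in self.endogenous:
            Psi[pos[v], pos[v]] = theta[k]
            k += 1
        for a, b in self.resid_covs:
            Psi[pos[a], pos[b]] = Psi[pos[b], pos[a]] = theta[k]
            k += 1
        return B, Psi

    def implied_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Sigma(theta) = (I-B)^-1 Psi (I-B)^-T (the path rule)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"expected {self.n_params} parameters, got {theta.shape}")
        B, Psi = self._unpack(theta)
        A = np.linalg.inv(np.eye(len(self.variables)) - B)
        return A @ Psi @ A.T

    def _start_values(self, data: pd.DataFrame) -> np.ndarray:
        """Least-squares start: per-equation OLS + sample exog moments."""
        theta = np.zeros(self.n_params)
        k = 0
        resid: dict[str, np.ndarray] = {}
        parents: dict[str, list[str]] = {}
        for c, e in self.edges:
            parents.setdefault(e, []).append(c)
        coefs: dict[tuple[str, str], float] = {}
        for e, ps in parents.items():
            X = data[ps].to_numpy()
            X = np.column_stack([np.ones(len(X)), X])
            y = data[e].to_numpy()
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid[e] = y - X @ b
            for c, bc in zip(ps, b[1:]):
                coefs[(c, e)] = float(bc)
        for c, e in self.edges:
            theta[k] = coefs[(c, e)]
            k += 1
        ex = self.exogenous
        if ex:
            Sx = np.atleast_2d(np.cov(data[ex].to_numpy(), rowvar=False,
                                      ddof=1))
            if self.exog_cov:
                for i in range(len(ex)):
                    for j in range(i + 1):
                        theta[k] = Sx[i, j]
                        k += 1
            else:
                for i in range(len(ex)):
                    theta[k] = Sx[i, i]
                    k += 1
        for v in self.endogenous:
            theta[k] = float(np.var(resid[v], ddof=1))
            k += 1
        for a, b in self.resid_covs:
            theta[k] = float(np.cov(resid[a], resid[b], ddof=1)[0, 1])
            k += 1
        return theta

    # -- estimation ----------------------------------------------------
    def fit(
        self,
        data: pd.DataFrame,
        n_restarts: int = 5,
        gtol: float = 1e-6,
        seed: int = 0,
    ) -> "SEMResults":
        """Fit by ML and attach Satorra-Bentler robust statistics.

        ``data`` must contain every model variable with complete cases;
        restarts jitter the least-squares start if BFGS stalls.
        """
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise KeyError(f"data lacks model variables: {missing}")
        X = data[self.variables].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("complete cases required (NaN present)")
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need n > p (n={n}, p={p})")
        if n < 5 * self.n_params:
            warnings.warn(
                f"n={n} < 5*q={5 * self.n_params}: estimates will be fragile",
                stacklevel=2)
        S = np.cov(X, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("singular sample covariance; remove a variable")

        def fml(theta: np.ndarray) -> float:
            try:
                Sigma = self.implied_covariance(theta)
            except np.linalg.LinAlgError:
                return 1e10
            s, logdet = np.linalg.slogdet(Sigma)
            if s <= 0:
                return 1e10
            try:
                inv = np.linalg.inv(Sigma)
            except np.linalg.LinAlgError:
                return 1e10
            return float(logdet + np.trace(S @ inv) - logdet_S - p)

        rng = np.random.default_rng(seed)
        x0 = self._start_values(data)
        best = None
        for attempt in range(n_restarts):
            start = x0 if attempt == 0 else x0 * (
                1 + 0.1 * rng.standard_normal(len(x0)))
            res = optimize.minimize(fml, start, method="BFGS",
                                    options={"gtol": gtol, "maxiter": 2000})
            gnorm = float(np.max(np.abs(res.jac)))
            if best is None or res.fun < best[0].fun:
                best = (res, gnorm)
            if gnorm < max(gtol, 1e-5 * max(1.0, abs(res.fun))):
                best = (res, gnorm)
                break
        res, gnorm = best
        # BFGS's 2-point gradients plateau near machine precision of F;
        # accept any stationary-enough optimum, refuse clear failures.
        if gnorm > 1e-3 and res.fun > 1e-8:
            raise SEMConvergenceError(
                f"no convergence after {n_restarts} restarts "
                f"(|grad|={gnorm:.2e})", best_x=res.x, grad_norm=gnorm)
        theta = res.x
        F = max(float(fml(theta)), 0.0)
        return SEMResults._build(self, data, theta, F, S)


# ------------------------------------------------------------- results
@dataclass
class SEMResults:
    """Estimates, robust statistics and fit indices for a PathModel."""

    model: PathModel
    params: pd.Series
    se: pd.Series
    se_robust: pd.Series
    n: int
    T_ML: float
    df: int
    scaling_factor: float
    T_SB: float
    p_value: float
    CFI: float
    AIC: float
    baseline: dict
    data: pd.DataFrame = field(repr=False)
    notes: list[str] = field(default_factory=list)

    # -- construction --------------------------------------------------
    @classmethod
    def _build(cls, model: PathModel, data: pd.DataFrame,
               theta: np.ndarray, F: float, S: np.ndarray) -> "SEMResults":
        X = data[model.variables].to_numpy(dtype=float)
        n, p = X.shape
        T_ML = (n - 1) * F
        df = model.df
        Sigma = model.implied_covariance(theta)
        D = duplication_matrix(p)
        Sinv = np.linalg.inv(Sigma)
        W = 0.5 * D.T @ np.kron(Sinv, Sinv) @ D
        Delta = _jacobian(model, theta)
        DtWD = Delta.T @ W @ Delta
        DtWD_inv = np.linalg.pinv(DtWD)
        acov = DtWD_inv / (n - 1)
        se = np.sqrt(np.clip(np.diag(acov), 0, None))

        Gamma = _gamma_adf(X)
        bread = DtWD_inv @ Delta.T @ W
        acov_r = bread @ Gamma @ bread.T / (n - 1)
        se_r = np.sqrt(np.clip(np.diag(acov_r), 0, None))

        notes: list[str] = []
        if df > 0:
            U = W - W @ Delta @ DtWD_inv @ Delta.T @ W
            c = float(np.trace(U @ Gamma)) / df
            c = max(c, 1e-12)
            T_SB = T_ML / c
            p_val = float(sps.chi2.sf(T_SB, df))
        else:
            c = 1.0
            T_SB = 0.0
            p_val = 1.0
            notes.append("df = 0: scaling undefined, T_SB reported as 0")

        base = _baseline_fit(S, Gamma, n, p)
        # CFI on the scaled statistics
        num = max(T_SB - df, 0.0)
        den = max(base["T_SB"] - base["df"], T_SB - df, 0.0)
        if den <= 0:
            CFI = 1.0
            notes.append("baseline no worse than model: CFI clamped to 1")
        else:
            CFI = 1.0 - num / den
        AIC = T_ML + 2 * model.n_params

        names = model.param_names
        return cls(
            model=model,
            params=pd.Series(theta, index=names),
            se=pd.Series(se, index=names),
            se_robust=pd.Series(se_r, index=names),
            n=n, T_ML=float(T_ML), df=df, scaling_factor=c,
            T_SB=float(T_SB), p_value=p_val, CFI=float(CFI),
            AIC=float(AIC), baseline=base, data=data, notes=notes,
        )

    # -- derived quantities --------------------------------------------
    @property
    def accepted(self) -> bool:
        """Acceptance rule: p(T_SB) > 0.05 and CFI > 0.95."""
        return self.p_value > 0.05 and self.CFI > 0.95

    @property
    def z_values(self) -> pd.Series:
        return self.params / self.se_robust.replace(0, np.nan)

    def standardized(self) -> pd.Series:
        """Edge coefficients rescaled by model-implied sds:
        b_std = b * sd(cause) / sd(effect)."""
        Sigma = self.model.implied_covariance(self.params.to_numpy())
        sd = np.sqrt(np.diag(Sigma))
        if (sd <= 0).any():
            bad = [v for v, s in zip(self.model.variables, sd) if s <= 0]
            raise ValueError(f"zero implied variance for {bad}")
        pos = {v: i for i, v in enumerate(self.model.variables)}
        out = {}
        for c, e in self.model.edges:
            b = self.params[f"{c}->{e}"]
            out[f"{c}->{e}"] = b * sd[pos[c]] / sd[pos[e]]
        return pd.Series(out)

    def conf_int(self, alpha: float = 0.05, robust: bool = True) -> pd.DataFrame:
        se = self.se_robust if robust else self.se
        zq = sps.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - zq * se, "upper": self.params + zq * se})

    def summary(self) -> str:
        std = self.standardized()
        lines = [
            "Path model fit (ML, Satorra-Bentler scaled)",
            "=" * 60,
            f"n = {self.n}   variables = {len(self.model.variables)}   "
            f"free params = {self.model.n_params}   df = {self.df}",
            f"T_ML = {self.T_ML:.3f}   scaling c = {self.scaling_factor:.3f}"
            f"   T_SB = {self.T_SB:.3f}   p = {self.p_value:.4f}",
            f"CFI = {self.CFI:.3f}   AIC = {self.AIC:.2f}   "
            f"accepted = {self.accepted}",
            "-" * 60,
            f"{'parameter':<24}{'est':>9}{'se(rob)':>9}{'z':>8}{'std':>9}",
        ]
        for name in self.params.index:
            z = self.z_values[name]
            s = std.get(name, np.nan)
            lines.append(
                f"{name:<24}{self.params[name]:>9.3f}"
                f"{self.se_robust[name]:>9.3f}"
                f"{z:>8.2f}" + (f"{s:>9.3f}" if np.isfinite(s) else "        -")
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        std = self.standardized()
        return pd.DataFrame({
            "estimate": self.params,
            "se": self.se,
            "se_robust": self.se_robust,
            "z": self.z_values,
            "standardized": std.reindex(self.params.index),
        })


# ---------------------------------------------------- internal numerics
def _jacobian(model: PathModel, theta: np.ndarray,
              eps: float = 1e-6) -> np.ndarray:
    """Delta = d vech Sigma / d theta by central differences."""
    base = vech(model.implied_covariance(theta))
    q = len(theta)
    Delta = np.zeros((len(base), q))
    for k in range(q):
        h = eps * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        Delta[:, k] = (vech(model.implied_covariance(tp))
                       - vech(model.implied_covariance(tm))) / (2 * h)
    return Delta


def _gamma_adf(X: np.ndarray) -> np.ndarray:
    """Empirical fourth-order moment matrix of vech(z z^T)."""
    Z = X - X.mean(axis=0)
    n, p = Z.shape
    idx = _vech_indices(p)
    Dn = np.empty((n, len(idx)))
    for k, (i, j) in enumerate(idx):
        Dn[:, k] = Z[:, i] * Z[:, j]
    Dn -= Dn.mean(axis=0)
    return Dn.T @ Dn / n


def _baseline_fit(S: np.ndarray, Gamma: np.ndarray, n: int, p: int) -> dict:
    """Independence model (free variances, zero covariances)."""
    sign, logdet_S = np.linalg.slogdet(S)
    F0 = float(np.sum(np.log(np.diag(S))) - logdet_S)
    T0 = (n - 1) * F0
    df0 = p * (p - 1) // 2
    D = duplication_matrix(p)
    Sigma0_inv = np.diag(1.0 / np.diag(S))
    W0 = 0.5 * D.T @ np.kron(Sigma0_inv, Sigma0_inv) @ D
    idx = _vech_indices(p)
    Delta0 = np.zeros((len(idx), p))
    for k, (i, j) in enumerate(idx):
        if i == j:
            Delta0[k, i] = 1.0
    DtWD0 = Delta0.T @ W0 @ Delta0
    U0 = W0 - W0 @ Delta0 @ np.linalg.pinv(DtWD0) @ Delta0.T @ W0
    c0 = float(np.trace(U0 @ Gamma)) / df0 if df0 > 0 else 1.0
    c0 = max(c0, 1e-12)
    return {"T_ML": float(T0), "df": df0, "c": c0,
            "T_SB": float(T0) / c0}


# ------------------------------------------------------------ utilities
def prepare_covariates(
    env: pd.DataFrame, precipitation: str = "precipitation"
) -> pd.DataFrame:
    """Replace precipitation by its natural log (heteroscedasticity guard).

    Other columns pass through unchanged; nonpositive precipitation is
    rejected naming the offending rows.
    """
    out = env.copy()
    if precipitation not in out.columns:
        return out
    bad = out.index[out[precipitation] <= 0].tolist()
    if bad:
        raise ValueError(
            f"nonpositive precipitation in rows {bad}: cannot take log")
    out[precipitation + "_log"] = np.log(out[precipitation])
    out = out.drop(columns=[precipitation])
    return out


def prune_model(
    model: PathModel, data: pd.DataFrame, seed: int = 0
) -> tuple[PathModel, SEMResults]:
    """Backward AIC elimination of redundant paths.

    Iteratively removes the single edge whose deletion most lowers AIC,
    stopping when no deletion lowers it; the returned fit carries the
    acceptance flag (p > 0.05 and CFI > 0.95).  AIC never increases
    between accepted steps (asserted).
    """
    current = model
    fit = current.fit(data, seed=seed)
    while len(current.edges) > 1:
        candidates = []
        for edge in current.edges:
            reduced = current.drop_edge(edge)
            # every endogenous variable must keep >= 1 incoming edge
            if set(reduced.endogenous) != set(current.endogenous):
                continue
            try:
                rfit = reduced.fit(data, seed=seed)
            except (SEMConvergenceError, ValueError):
                continue
            candidates.append((rfit.AIC, edge, reduced, rfit))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        best_aic, _, best_model, best_fit = candidates[0]
        if best_aic >= fit.AIC:
            break
        assert best_aic < fit.AIC
        current, fit = best_model, best_fit
    return current, fit
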