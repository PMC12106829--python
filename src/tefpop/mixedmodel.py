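"""REML linear mixed model for multi-location augmented trials.

The model for a (possibly transformed) plot-level trait value is

    f(y) = alpha + location (fixed) + block-within-location (random)
           + genotype (random) + residual,

with independent zero-mean random effects: block-within-location with
variance ``sigma2_block``, genotype with variance ``sigma2_g``, and residual
``sigma2_e``.  Location is fixed because there are few levels; the augmented
design (unreplicated entries plus replicated checks) makes the genotype
effect estimable only as a random effect, via BLUP.

REML estimation is a derivative-free search (Nelder-Mead) over log variance
components with an exact restricted-likelihood evaluation.  BLUPs and their
prediction-error variance (PEV) matrix come from the estimated variance
structure; BLUEs come from a genotype-as-fixed generalised least squares
refit.  Two broad-sense heritability estimators are provided: the Cullis
form ``1 - mean pairwise Var(BLUP difference) / (2 sigma2_g)`` and the
regression (Walsh-Lynch) form, the slope of BLUPs on mean-centred BLUEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import skew

_TRANSFORMS = {
    "none": (lambda x: x, lambda x: x),
    "sqrt": (np.sqrt, lambda x: x ** 2),
    "ln": (np.log, np.exp),
}

_LOGVAR_FLOOR = -25.0  # exp(-25) ~ 1.4e-11: effectively a zero component


def transform_values(values: np.ndarray, transformation: str,
                     plot_ids=None) -> np.ndarray:
    """Apply the normalising transformation, naming offending plots on error."""
    if transformation not in _TRANSFORMS:
        raise ValueError(f"unknown transformation {transformation!r}")
    values = np.asarray(values, dtype=float)
    if transformation == "sqrt" and (values < 0).any():
        bad = _name_plots(values < 0, plot_ids)
        raise ValueError(f"sqrt transform undefined for negative values at plots {bad}")
    if transformation == "ln" and (values <= 0).any():
        bad = _name_plots(values <= 0, plot_ids)
        raise ValueError(f"ln transform undefined for non-positive values at plots {bad}")
    return _TRANSFORMS[transformation][0](values)


def inverse_transform(values: np.ndarray, transformation: str) -> np.ndarray:
    if transformation not in _TRANSFORMS:
        raise ValueError(f"unknown transformation {transformation!r}")
    return _TRANSFORMS[transformation][1](np.asarray(values, dtype=float))


def _name_plots(mask: np.ndarray, plot_ids) -> list:
    if plot_ids is None:
        return list(np.flatnonzero(mask)[:10])
    return list(np.asarray(plot_ids)[mask][:10])


def _dummies(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(labels))
    Z = (labels.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    return Z, levels


@dataclass
class TrialMixedModelResults:
    """Fitted variance components, effects and heritabilities.

    Attributes
    ----------
    sigma2_block, sigma2_g, sigma2_e : float
        REML variance components.
    fixed_effects : pandas.Series
        Intercept and location effects (first location is the baseline).
    blups : pandas.Series
        Genotype BLUPs (sum to ~0).
    pev : pandas.DataFrame
        Prediction-error variance/covariance matrix of the BLUPs.
    blues : pandas.Series
        Genotype BLUEs from the genotype-as-fixed refit.
    h2_cullis, h2_regression : float
        Broad-sense heritability estimates, clamped to [0, 1].
    """

    trait: str
    transformation: str
    sigma2_block: float
    sigma2_g: float
    sigma2_e: float
    fixed_effects: pd.Series
    blups: pd.Series
    pev: pd.DataFrame
    blues: pd.Series
    h2_cullis: float
    h2_regression: float
    n_plots: int
    n_genotypes: int
    converged: bool
    n_iter: int
    reml_loglik: float
    dropped_terms: list[str] = field(default_factory=list)

    def blups_with_intercept(self) -> pd.Series:
        """BLUPs shifted by the global intercept (presentation only)."""
        return self.blups + self.fixed_effects["intercept"]

    def summary(self) -> str:
        lines = [
            f"Trial mixed model: trait={self.trait} "
            f"(transformation={self.transformation})",
            f"  plots={self.n_plots}  genotypes={self.n_genotypes}  "
            f"converged={self.converged} (iter={self.n_iter})",
            f"  REML log-likelihood: {self.reml_loglik:.4f}",
            "  Variance components:",
            f"    sigma2_block = {self.sigma2_block:.6g}",
            f"    sigma2_g     = {self.sigma2_g:.6g}",
            f"    sigma2_e     = {self.sigma2_e:.6g}",
            "  Heritability:",
            f"    H2 (Cullis)           = {self.h2_cullis:.4f}",
            f"    H2 (BLUP-BLUE slope)  = {self.h2_regression:.4f}",
            "  Fixed effects:",
        ]
        for k, v in self.fixed_effects.items():
            lines.append(f"    {k:<20s} {v: .6g}")
        if self.dropped_terms:
            lines.append(f"  Dropped terms: {', '.join(self.dropped_terms)}")
        return "\n".join(lines)


class TrialMixedModel:
    """Location-fixed, block- and genotype-random mixed model for one trait.

    Parameters
    ----------
    data : pandas.DataFrame
        Plot-level table with columns ``location``, ``block``, ``accession``
        and the trait column.
    trait : str
        Trait column to model.
    transformation : {"none", "sqrt", "ln", "auto"}
        Normalising transformation applied before fitting; ``"auto"`` picks
        the member of {none, sqrt, ln} minimising |skewness| of ordinary
        least-squares residuals.
    drop_locations : list of str, optional
        Locations excluded for this trait before fitting.
    """

    def __init__(self, data: pd.DataFrame, trait: str,
                 transformation: str = "none",
                 drop_locations: list[str] | None = None) -> None:
        required = {"location", "block", "accession", trait}
        missing_cols = required - set(data.columns)
        if missing_cols:
            raise ValueError(f"phenotype table lacks columns {sorted(missing_cols)}")
        cols = ["location", "block", "accession", trait]
        if "plot_id" in data.columns:
            cols.append("plot_id")
        df = data.loc[data[trait].notna(), cols].copy()
        if drop_locations:
            df = df[~df["location"].isin(drop_locations)]
        if df.empty:
            raise ValueError(f"no observations for trait {trait!r}")
        self.data = df.reset_index(drop=True)
        self.trait = trait
        self.dropped_terms: list[str] = []
        if transformation == "auto":
            transformation = self._pick_transformation()
        self.transformation = transformation
        plot_ids = (self.data["plot_id"].to_numpy()
                    if "plot_id" in self.data.columns else None)
        self.y = transform_values(self.data[trait].to_numpy(), transformation,
                                  plot_ids)
        self._build_design()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str,
                       **kwargs) -> "TrialMixedModel":
        return cls(data, trait, **kwargs)

    # -- design ------------------------------------------------------------
    def _pick_transformation(self) -> str:
        best, best_skew = "none", np.inf
        for name in ("none", "sqrt", "ln"):
            vals = self.data[self.trait].to_numpy(dtype=float)
            if name == "sqrt" and (vals < 0).any():
                continue
            if name == "ln" and (vals <= 0).any():
                continue
            y = _TRANSFORMS[name][0](vals)
            resid = y - pd.Series(y).groupby(
                self.data["accession"].to_numpy()).transform("mean").to_numpy()
            s = abs(skew(resid)) if np.ptp(resid) > 0 else 0.0
            if s < best_skew:
                best, best_skew = name, s
        return best

    def _build_design(self) -> None:
        df = self.data
        locs = sorted(pd.unique(df["location"]))
        n = len(df)
        if len(locs) >= 2:
            X = np.ones((n, len(locs)))
            for j, loc in enumerate(locs[1:], start=1):
                X[:, j] = (df["location"] == loc).astype(float)
            names = ["intercept"] + [f"location[{loc}]" for loc in locs[1:]]
        else:
            X = np.ones((n, 1))
            names = ["intercept"]
            if len(locs) == 1:
                self.dropped_terms.append("location (single level)")
        self.X, self.fixed_names = X, names

        blk = df["location"].astype(str) + ":" + df["block"].astype(str)
        Zb, blk_levels = _dummies(blk)
        if len(blk_levels) < 2:
            self.dropped_terms.append("block (single level)")
            warnings.warn("block term dropped: only one level", stacklevel=2)
            Zb = None
        self.Zb = Zb

        Zg, geno_levels = _dummies(df["accession"].astype(str))
        if len(geno_levels) < 2:
            raise ValueError("genotype factor has a single level")
        self.Zg, self.genotypes = Zg, geno_levels

    # -- REML machinery ----------------------------------------------------
    def _reml_neg_loglik(self, logvars: np.ndarray) -> float:
        s2b, s2g, s2e = np.exp(np.clip(logvars, _LOGVAR_FLOOR, 20.0))
        n = len(self.y)
        V = s2e * np.eye(n) + s2g * (self.Zg @ self.Zg.T)
        if self.Zb is not None:
            V += s2b * (self.Zb @ self.Zb.T)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, self.y)
        Vi_X = np.linalg.solve(V, self.X)
        XtViX = self.X.T @ Vi_X
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(XtViX, self.X.T @ Vi_y)
        resid_quad = self.y @ Vi_y - (self.X.T @ Vi_y) @ beta
        return 0.5 * (logdetV + logdetXtViX + resid_quad)

    def fit(self, tol: float = 1e-8, maxiter: int = 2000) -> TrialMixedModelResults:
        """REML fit; returns the results object with BLUPs, BLUEs and H2."""
        y = self.y
        if np.ptp(y) == 0:
            return self._degenerate_results()
        vy = y.var(ddof=1)
        x0 = np.log(np.array([vy / 4, vy / 2, vy / 2]))
        opt = minimize(self._reml_neg_loglik, x0, method="Nelder-Mead",
                       options={"fatol": tol, "xatol": 1e-8,
                                "maxiter": maxiter, "maxfev": maxiter})
        s2b, s2g, s2e = np.exp(np.clip(opt.x, _LOGVAR_FLOOR, 20.0))
        if self.Zb is None:
            s2b = 0.0
        # snap effectively-zero boundary estimates to exactly zero
        snap = 1e-8 * max(vy, 1.0)
        s2b = 0.0 if s2b < snap else float(s2b)
        s2g = 0.0 if s2g < snap else float(s2g)
        return self._results_at(s2b, s2g, float(s2e), opt)

    def _degenerate_results(self) -> TrialMixedModelResults:
        m = len(self.genotypes)
        zeros = pd.Series(0.0, index=self.genotypes)
        fx = pd.Series(0.0, index=self.fixed_names)
        fx["intercept"] = float(self.y[0])
        return TrialMixedModelResults(
            self.trait, self.transformation, 0.0, 0.0, 0.0, fx, zeros,
            pd.DataFrame(np.zeros((m, m)), index=self.genotypes,
                         columns=self.genotypes),
            pd.Series(float(self.y[0]), index=self.genotypes),
            0.0, 0.0, len(self.y), m, True, 0, 0.0,
            list(self.dropped_terms) + ["all values identical"])

    def _results_at(self, s2b: float, s2g: float, s2e: float,
                    opt) -> TrialMixedModelResults:
        y, X, Zg = self.y, self.X, self.Zg
        n = len(y)
        V = s2e * np.eye(n) + s2g * (Zg @ Zg.T)
        if self.Zb is not None and s2b > 0:
            V += s2b * (self.Zb @ self.Zb.T)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        XtViX_inv = np.linalg.inv(XtViX)
        beta = XtViX_inv @ (X.T @ Vi @ y)
        P = Vi - Vi @ X @ XtViX_inv @ X.T @ Vi
        # BLUPs u_hat = s2g * Zg' P y ; PEV = G - G Zg' P Zg G with G = s2g I
        u = s2g * (Zg.T @ (P @ y))
        m = len(self.genotypes)
        pev = s2g * np.eye(m) - (s2g ** 2) * (Zg.T @ P @ Zg)
        blups = pd.Series(u, index=self.genotypes)
        pev_df = pd.DataFrame(pev, index=self.genotypes, columns=self.genotypes)
        blues = self._fit_blues(s2b, s2e)
        h2c = _cullis_h2(pev, s2g)
        h2r = _regression_h2(blups, blues)
        return TrialMixedModelResults(
            self.trait, self.transformation, s2b, s2g, s2e,
            pd.Series(beta, index=self.fixed_names), blups, pev_df, blues,
            h2c, h2r, n, m, bool(opt.success), int(opt.nit),
            float(-opt.fun), list(self.dropped_terms))

    def _fit_blues(self, s2b: float, s2e: float) -> pd.Series:
        """Genotype-as-fixed GLS refit; returns per-genotype BLUEs.

        The covariance uses the block and residual components re-estimated
        with genotype fixed (2-parameter REML), falling back to the supplied
        components if that refit is degenerate.
        """
        y = self.y
        n = len(y)
        # fixed design: genotype dummies + non-baseline location columns
        XF = np.hstack([self.Zg, self.X[:, 1:]])
        if self.Zb is not None:
            s2b_f, s2e_f = self._reml_blue_components(XF, s2b, s2e)
            V = s2e_f * np.eye(n) + s2b_f * (self.Zb @ self.Zb.T)
        else:
            V = max(s2e, 1e-12) * np.eye(n)
        Vi = np.linalg.inv(V)
        A = XF.T @ Vi @ XF
        bhat = np.linalg.lstsq(A, XF.T @ Vi @ y, rcond=None)[0]
        blues = bhat[:len(self.genotypes)]
        # express BLUEs on the first-location scale (genotype + baseline)
        return pd.Series(blues, index=self.genotypes)

    def _reml_blue_components(self, XF: np.ndarray, s2b0: float,
                              s2e0: float) -> tuple[float, float]:
        y, Zb = self.y, self.Zb
        n = len(y)
        ZZt = Zb @ Zb.T

        def nll(logvars):
            b, e = np.exp(np.clip(logvars, _LOGVAR_FLOOR, 20.0))
            V = e * np.eye(n) + b * ZZt
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e12
            Vi_y = np.linalg.solve(V, y)
            Vi_X = np.linalg.solve(V, XF)
            A = XF.T @ Vi_X
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return 1e12
            bhat = np.linalg.lstsq(A, XF.T @ Vi_y, rcond=None)[0]
            quad = y @ Vi_y - (XF.T @ Vi_y) @ bhat
            return 0.5 * (2 * np.log(np.diag(L)).sum() + logdetA + quad)

        x0 = np.log([max(s2b0, 1e-6), max(s2e0, 1e-6)])
        opt = minimize(nll, x0, method="Nelder-Mead",
                       options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": 1000})
        b, e = np.exp(np.clip(opt.x, _LOGVAR_FLOOR, 20.0))
        return float(b), float(max(e, 1e-12))


def _cullis_h2(pev: np.ndarray, s2g: float) -> float:
    """Cullis broad-sense heritability from the pairwise BLUP-difference PEV."""
    if s2g <= 0:
        return 0.0
    m = pev.shape[0]
    diag = np.diag(pev)
    # mean over i<j of Var(u_i - u_j) = PEV_ii + PEV_jj - 2 PEV_ij;
    # sum_{i<j}(d_i + d_j) = (m-1) sum(d), sum_{i<j} 2 c_ij = offdiagonal sum
    offdiag = pev.sum() - diag.sum()
    total = (m - 1) * diag.sum() - offdiag
    vbar = total / (m * (m - 1) / 2)
    return float(np.clip(1.0 - vbar / (2.0 * s2g), 0.0, 1.0))


def _regression_h2(blups: pd.Series, blues: pd.Series) -> float:
    """Walsh-Lynch heritability: slope of BLUPs on mean-centred BLUEs."""
    x = blues.reindex(blups.index).to_numpy()
    x = x - x.mean()
    u = blups.to_numpy()
    denom = (x ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.clip((x * u).sum() / denom, 0.0, 1.0))


def heritability(result: TrialMixedModelResults) -> dict[str, float]:
    """Both broad-sense heritability estimators from a fitted model."""
    if result.pev is None:
        raise ValueError("fit carries no PEV matrix")
    return {"h2_cullis": result.h2_cullis,
            "h2_regression": result.h2_regression}
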