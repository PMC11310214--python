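"""Two-site-class isothermal titration calorimetry (ITC) model.

Dopamine titrated into DNA-wrapped nanotube suspensions shows two
thermodynamically distinct site populations: a strong class on the exposed
nanotube surface (large enthalpic footprint, saturating) and a weak class in
the DNA corona (small footprint, often not saturating at 100 uM). The model
here is the standard two independent site classes binding polynomial: with
free ligand ``L``, macromolecule concentration ``M`` and classes
``c in {1, 2}`` carrying ``n_c`` sites of affinity ``K_c`` (M^-1),

    bound_c = M * n_c * K_c * L / (1 + K_c * L)
    L_total = L + sum_c bound_c          (one monotone scalar root per step)

Injection heats follow from the change in bound ligand with the standard
perfusion-cell displacement correction; the heat of injection ``i`` is
``V_cell * sum_c dH_c * (B_c,i - B_c,i-1 * (1 - dV_i/V_cell))`` plus a
constant per-injection offset.

Usage is statsmodels-flavoured::

    model = TwoSiteBindingModel(experiment)
    res = model.fit()
    print(res.summary())
    res.stoichiometry_report()   # e.g. "1:37"
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .errors import FitError, ValidationError

__all__ = [
    "ItcExperiment",
    "SiteClassParams",
    "TwoClassFit",
    "simulate_heats",
    "TwoSiteBindingModel",
    "TwoSiteBindingResults",
    "fit_two_class",
    "stoichiometry_report",
]

KCAL_TO_UCAL = 1e9  # kcal -> ucal


@dataclass
class ItcExperiment:
    """One titration: injection protocol plus measured heats.

    Volumes in uL, concentrations in M (macromolecule = the nanotube, so
    stoichiometries are sites per nanotube), cell volume in mL, heats in
    ucal per injection.
    """

    injection_volumes: np.ndarray
    syringe_conc: float
    cell_conc: float
    cell_volume: float
    heats: np.ndarray | None = None
    temperature: float = 297.15
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if np.any(self.injection_volumes <= 0):
            raise ValidationError("injection volumes must be > 0")
        if self.syringe_conc <= 0 or self.cell_conc <= 0 or self.cell_volume <= 0:
            raise ValidationError("concentrations and cell volume must be > 0")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise ValidationError("heats must match injection count")
            if not np.all(np.isfinite(self.heats)):
                raise ValidationError("heats must be finite")

    @property
    def n_injections(self) -> int:
        return self.injection_volumes.size


@dataclass
class SiteClassParams:
    """Thermodynamic parameters of the two independent site classes."""

    n1: float
    K1: float
    dH1: float
    n2: float = 0.0
    K2: float = 1.0
    dH2: float = 0.0
    offset: float = 0.0  # ucal per injection

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValidationError("site numbers must be >= 0")
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValidationError("binding constants must be > 0")


@dataclass
class TwoClassFit:
    """Fitted two-class parameters with uncertainties and diagnostics."""

    params: SiteClassParams
    stderr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    redchi: float
    rss: float
    n_obs: int
    n_varys: int
    success: bool
    class2_saturation: float  # occupancy of class 2 at the final injection
    message: str = ""


def _totals(protocol: ItcExperiment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell concentrations after each injection (dilution is binding-independent)."""
    v0 = protocol.cell_volume * 1e-3  # L
    dv = protocol.injection_volumes * 1e-6 / v0
    dilution = 1.0 - dv
    m_tot = protocol.cell_conc * np.cumprod(dilution)
    l_tot = np.empty_like(m_tot)
    acc = 0.0
    for i in range(dv.size):
        acc = acc * dilution[i] + protocol.syringe_conc * dv[i]
        l_tot[i] = acc
    return m_tot, l_tot, dilution


def _free_ligand_vec(
    l_tot: np.ndarray, m_tot: np.ndarray, p: SiteClassParams, tol: float = 1e-14
) -> np.ndarray:
    """Solve the two-class mass balance for free ligand at every injection.

    The balance ``f(L) = L + sum_c M n_c K_c L/(1+K_c L) - L_tot`` is
    increasing and concave in L >= 0, so Newton iteration from either side
    of the root converges monotonically without overshoot; we start at the
    upper bracket ``L = L_tot``.
    """
    L = l_tot.copy()
    for _ in range(200):
        s1 = 1.0 + p.K1 * L
        s2 = 1.0 + p.K2 * L
        f = (
            L
            + m_tot * p.n1 * p.K1 * L / s1
            + m_tot * p.n2 * p.K2 * L / s2
            - l_tot
        )
        if np.all(np.abs(f) < tol):
            break
        fp = 1.0 + m_tot * p.n1 * p.K1 / s1**2 + m_tot * p.n2 * p.K2 / s2**2
        L = np.clip(L - f / fp, 0.0, l_tot)
    else:  # pragma: no cover - Newton is monotone here
        raise FitError(
            f"free-ligand solve did not reach |residual| < {tol:g} M; "
            f"max residual {np.abs(f).max():.3e}"
        )
    return L


def simulate_heats(
    params: SiteClassParams, protocol: ItcExperiment
) -> np.ndarray:
    """Forward model: per-injection heats (ucal) for the given protocol.

    Each injection dilutes cell contents by ``1 - dV/V0`` (perfusion-cell
    displacement), adds syringe ligand, re-equilibrates the two-class mass
    balance, and releases ``V0 * sum_c dH_c * (B_c,i - B_c,i-1*(1-dV/V0))``
    plus the constant offset.
    """
    v0 = protocol.cell_volume * 1e-3  # L
    m_tot, l_tot, dilution = _totals(protocol)
    L = _free_ligand_vec(l_tot, m_tot, params)
    b1 = m_tot * params.n1 * params.K1 * L / (1.0 + params.K1 * L)
    b2 = m_tot * params.n2 * params.K2 * L / (1.0 + params.K2 * L)
    b1_prev = np.concatenate([[0.0], b1[:-1]])
    b2_prev = np.concatenate([[0.0], b2[:-1]])
    dq = params.dH1 * (b1 - b1_prev * dilution) + params.dH2 * (b2 - b2_prev * dilution)
    return v0 * dq * KCAL_TO_UCAL + params.offset


def _final_occupancy(params: SiteClassParams, protocol: ItcExperiment) -> float:
    """Class-2 fractional occupancy after the last injection."""
    m_tot, l_tot, _ = _totals(protocol)
    L = float(_free_ligand_vec(l_tot[-1:], m_tot[-1:], params)[0])
    return params.K2 * L / (1 + params.K2 * L)


class TwoSiteBindingResults:
    """Results of a fitted two-site-class ITC model."""

    def __init__(self, fit: TwoClassFit, model: "TwoSiteBindingModel"):
        self._fit = fit
        self.model = model

    @property
    def params(self) -> SiteClassParams:
        return self._fit.params

    @property
    def stderr(self) -> dict[str, float]:
        return self._fit.stderr

    @property
    def ci95(self) -> dict[str, tuple[float, float]]:
        return self._fit.ci95

    @property
    def redchi(self) -> float:
        return self._fit.redchi

    @property
    def success(self) -> bool:
        return self._fit.success

    @property
    def class2_nonsaturating(self) -> bool:
        """True when class 2 has not reached 90% occupancy at the end."""
        return self._fit.class2_saturation < 0.9

    def as_fit(self) -> TwoClassFit:
        return self._fit

    def predict(self, protocol: ItcExperiment | None = None) -> np.ndarray:
        return simulate_heats(self.params, protocol or self.model.experiment)

    def class2_significance(self) -> float:
        """Nested-model F-test p-value for the class-2 contribution.

        Refits with class 2 removed (n2 = dH2 = 0) and compares residual
        sums of squares; a large p means the data do not support a second
        site class.
        """
        reduced = self.model._fit_reduced()
        full = self._fit
        df_full = full.n_obs - full.n_varys
        extra = full.n_varys - reduced.n_varys
        if df_full <= 0 or extra <= 0:
            raise FitError("degrees of freedom exhausted; cannot test class 2")
        num = max(reduced.rss - full.rss, 0.0) / extra
        den = full.rss / df_full
        if den == 0:
            return 0.0 if num > 0 else 1.0
        f_stat = num / den
        return float(stats.f.sf(f_stat, extra, df_full))

    def stoichiometry_report(self) -> dict:
        return stoichiometry_report(self)

    def summary(self) -> str:
        p, f = self.params, self._fit
        def line(name, val, unit=""):
            se = f.stderr.get(name)
            se_s = f"+/- {se:.3g}" if se is not None and np.isfinite(se) else "(se n/a)"
            return f"{name:>8s}: {val: .5g} {se_s} {unit}"
        lines = [
            "Two-site-class ITC binding fit",
            "=" * 50,
            f"injections used: {f.n_obs} (of {self.model.experiment.n_injections})",
            line("n1", p.n1, "sites/SWCNT"),
            line("K1", p.K1, "1/M"),
            line("dH1", p.dH1, "kcal/mol"),
            line("n2", p.n2, "sites/SWCNT"),
            line("K2", p.K2, "1/M"),
            line("dH2", p.dH2, "kcal/mol"),
            line("offset", p.offset, "ucal"),
            f"reduced chi-square: {f.redchi:.4g}",
            f"class-2 saturation at final injection: {f.class2_saturation:.2f}"
            + ("  [non-saturating]" if self.class2_nonsaturating else ""),
            "=" * 50,
        ]
        return "\n".join(lines)


class TwoSiteBindingModel:
    """Fit the two-independent-classes binding model to titration heats.

    Parameters
    ----------
    experiment : ItcExperiment
        Protocol with measured heats (>= 8 injections).
    skip_first : bool
        Exclude the first injection from the residuals (standard practice:
        the first aliquot is diluted by syringe backlash).
    sigma : float or None
        Per-point heat uncertainty (ucal) for weighted least squares.
    """

    _PARAM_NAMES = ("n1", "K1", "dH1", "n2", "K2", "dH2", "offset")

    def __init__(
        self,
        experiment: ItcExperiment,
        skip_first: bool = True,
        sigma: float | None = None,
    ):
        if experiment.heats is None:
            raise ValidationError("experiment carries no measured heats")
        if experiment.n_injections < 8:
            raise ValidationError("need at least 8 injections for a two-class fit")
        self.experiment = experiment
        self.skip_first = skip_first
        self.sigma = sigma
        self._mask = np.ones(experiment.n_injections, dtype=bool)
        if skip_first:
            self._mask[0] = False

    # -- internals ---------------------------------------------------------

    def _residual(self, lmpars: lmfit.Parameters, two_class: bool) -> np.ndarray:
        v = lmpars.valuesdict()
        p = SiteClassParams(
            n1=v["n1"], K1=10 ** v["logK1"], dH1=v["dH1"],
            n2=v["n2"] if two_class else 0.0,
            K2=10 ** v["logK2"] if two_class else 1.0,
            dH2=v["dH2"] if two_class else 0.0,
            offset=v["offset"],
        )
        model = simulate_heats(p, self.experiment)
        resid = (model - self.experiment.heats)[self._mask]
        if self.sigma:
            resid = resid / self.sigma
        return resid

    def _initial_grid(self) -> list[dict]:
        heats = self.experiment.heats
        scale = float(np.abs(heats[self._mask]).max())
        # crude enthalpy scale: total heat over total strong sites guess
        dh_guess = -abs(scale) / max(
            self.experiment.cell_conc * 20 * self.experiment.cell_volume * 1e-3 * KCAL_TO_UCAL,
            1e-30,
        )
        dh_guess = float(np.clip(dh_guess, -20, -0.5))
        sign = -1.0 if heats[self._mask][:3].mean() < 0 else 1.0
        return [
            dict(
                n1=20.0, logK1=logk1, dH1=sign * abs(dh_guess),
                n2=40.0, logK2=logk1 - 2.0, dH2=sign * abs(dh_guess) / 4,
                offset=0.0,
            )
            for logk1 in (5.5, 6.5, 7.5)
        ]

    def _make_params(self, init: dict, two_class: bool) -> lmfit.Parameters:
        # bounds encode the model's premises: enthalpies in the physical
        # noncovalent range, affinities in the ITC-measurable window, and
        # class 1 at least one decade tighter than class 2 (without the
        # separation constraint the optimizer can split the strong
        # transition between both classes and overfit noise)
        pars = lmfit.Parameters()
        pars.add("n1", value=init["n1"], min=1e-3, max=1e4)
        pars.add("logK1", value=init["logK1"], min=2.0, max=9.0)
        pars.add("dH1", value=init["dH1"], min=-30, max=30)
        pars.add("n2", value=init["n2"], min=0.0, max=1e4, vary=two_class)
        pars.add(
            "dlogK",
            value=max(init["logK1"] - init["logK2"], 1.0),
            min=1.0, max=8.0, vary=two_class,
        )
        pars.add("logK2", expr="logK1 - dlogK")
        pars.add("dH2", value=init["dH2"], min=-30, max=30, vary=two_class)
        pars.add("offset", value=init["offset"], min=-50, max=50)
        return pars

    def _fit_once(self, init: dict, two_class: bool):
        pars = self._make_params(init, two_class)
        return lmfit.minimize(
            self._residual, pars, args=(two_class,), method="least_squares",
            x_scale="jac", nan_policy="raise",
        )

    def _collect(self, result, two_class: bool) -> TwoClassFit:
        v = result.params.valuesdict()
        p = SiteClassParams(
            n1=v["n1"], K1=10 ** v["logK1"], dH1=v["dH1"],
            n2=v["n2"] if two_class else 0.0,
            K2=10 ** v["logK2"] if two_class else 1.0,
            dH2=v["dH2"] if two_class else 0.0,
            offset=v["offset"],
        )
        # class 1 is the higher-affinity class by convention
        if two_class and p.K2 > p.K1 and p.n2 > 0:
            p = SiteClassParams(
                n1=p.n2, K1=p.K2, dH1=p.dH2, n2=p.n1, K2=p.K1, dH2=p.dH1,
                offset=p.offset,
            )
            swap = {"n1": "n2", "n2": "n1", "dH1": "dH2", "dH2": "dH1",
                    "logK1": "logK2", "logK2": "logK1"}
        else:
            swap = {}
        stderr: dict[str, float] = {}
        ci95: dict[str, tuple[float, float]] = {}
        for name in ("n1", "n2", "dH1", "dH2", "offset", "logK1", "logK2"):
            par = result.params[swap.get(name, name)]
            if par.stderr is not None:
                val = par.value
                if name.startswith("logK"):
                    # report K-scale error via the delta method
                    k = 10 ** val
                    se = k * np.log(10) * par.stderr
                    key = "K" + name[-1]
                    stderr[key] = float(se)
                    ci95[key] = (float(k - 1.96 * se), float(k + 1.96 * se))
                else:
                    stderr[name] = float(par.stderr)
                    ci95[name] = (
                        float(val - 1.96 * par.stderr),
                        float(val + 1.96 * par.stderr),
                    )
        rss = float(np.sum(np.asarray(result.residual) ** 2))
        if self.sigma:
            rss *= self.sigma**2
        return TwoClassFit(
            params=p, stderr=stderr, ci95=ci95,
            redchi=float(result.redchi), rss=rss,
            n_obs=int(result.ndata), n_varys=int(result.nvarys),
            success=bool(result.success),
            class2_saturation=_final_occupancy(p, self.experiment),
            message=str(result.message),
        )

    def _data_driven_start(self) -> dict | None:
        """Seed the two-class grid from a one-class (Wiseman) fit."""
        try:
            one = self._fit_best_over(self._initial_grid()[::2], two_class=False)
        except FitError:
            return None
        p = one.params
        return dict(
            n1=max(p.n1 * 0.8, 1.0), logK1=float(np.log10(p.K1)), dH1=p.dH1,
            n2=max(p.n1 * 0.5, 1.0), logK2=float(np.log10(p.K1)) - 2.0,
            dH2=p.dH1 / 5, offset=p.offset,
        )

    def _fit_best(self, two_class: bool) -> TwoClassFit:
        starts = self._initial_grid()
        if two_class:
            extra = self._data_driven_start()
            if extra is not None:
                starts = [extra] + starts
        return self._fit_best_over(starts, two_class)

    def _fit_best_over(self, starts: list[dict], two_class: bool) -> TwoClassFit:
        best, best_rss = None, np.inf
        errors: list[str] = []
        for init in starts:
            try:
                result = self._fit_once(init, two_class)
            except Exception as exc:
                errors.append(str(exc))
                continue
            rss = float(np.sum(np.asarray(result.residual) ** 2))
            if result.success and rss < best_rss:
                best, best_rss = result, rss
        if best is None:
            raise FitError("no start converged; errors: " + "; ".join(errors[:3]))
        return self._collect(best, two_class)

    def _fit_reduced(self) -> TwoClassFit:
        return self._fit_best(two_class=False)

    # -- public ------------------------------------------------------------

    def fit(self) -> TwoSiteBindingResults:
        """Multi-start weighted least squares over a deterministic init grid."""
        return TwoSiteBindingResults(self._fit_best(two_class=True), self)


def fit_two_class(
    experiment: ItcExperiment, **kwargs
) -> TwoSiteBindingResults:
    """Functional front end: fit the two-class model to an experiment."""
    return TwoSiteBindingModel(experiment, **kwargs).fit()


def stoichiometry_report(fit: TwoSiteBindingResults | TwoClassFit) -> dict:
    """Per-nanotube stoichiometry of the strong site class, as '1:n'.

    Returns a dict with the rounded site count, the ratio string and, when a
    CI is available, a ratio range string like ``'1:30 to 1:40'``.
    """
    f = fit.as_fit() if isinstance(fit, TwoSiteBindingResults) else fit
    if not f.success:
        raise FitError("fit did not converge; refusing to report stoichiometry")
    n1 = f.params.n1
    out = {"n1": n1, "n1_rounded": int(round(n1)), "ratio": f"1:{int(round(n1))}"}
    ci = f.ci95.get("n1")
    if ci is not None and all(np.isfinite(ci)):
        lo, hi = (int(round(ci[0])), int(round(ci[1])))
        out["ci95"] = (float(ci[0]), float(ci[1]))
        out["ratio_range"] = f"1:{lo} to 1:{hi}"
    return out
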