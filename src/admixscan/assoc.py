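"""Mixed-model GWA separating ancestral-origin from residual allele effects.

Model
-----
For repeated records ``y`` (e.g. milk-yield deviations) of admixed animals,

    y = 1 mu + X beta + W u + W pe + e

where ``beta`` holds two per-SNP fixed effects estimated jointly: the
ancestral-origin effect (per EUT-origin allele copy, dosage 0/1/2 from
local ancestry) and the residual allele effect (per alternate-allele copy,
after accounting for origin); ``u ~ N(0, G sigma_g2)`` is the polygenic
animal effect under a leave-one-chromosome-out (LOCO) GRM, ``pe ~ N(0, I
sigma_pe2)`` the permanent-environment animal effect, ``e ~ N(0, I
sigma_e2)`` the record residual, and ``W`` the record-to-animal incidence
shared by ``u`` and ``pe``.

Fitting strategy
----------------
Variance components are estimated once per LOCO GRM by REML under the
intercept-only null, then every SNP on the excluded chromosome is tested
by generalized least squares with the variance structure held fixed (the
EMMAX two-stage approximation); ``fit_reml`` also supports arbitrary fixed
effects so a full per-SNP refit is available as an exact cross-check.

The restricted likelihood is evaluated on an exact collapse of the
repeated-records model: within-animal contrasts depend only on
``sigma_e2`` (their sum of squares enters as ``SSW / sigma_e2`` with
``N - m`` degrees of freedom), while animal means follow ``ybar ~ N(X
beta, sigma_g2 G + sigma_pe2 I + sigma_e2 D^-1)`` with ``D`` the diagonal
of record counts.  Both effects are tested with Wald statistics against
chi-square with one degree of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .panel import AncestryMatrix, HaplotypePanel, PhenotypeTable
from .relatedness import GRM, build_grm
from .ancestry import eut_dosage

__all__ = [
    "VarianceComponents",
    "SnpAssocRecord",
    "ConvergenceError",
    "fit_reml",
    "fit_null_reml",
    "SnpTester",
    "gwa_scan",
]

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class VarianceComponents:
    """REML estimates of the three variance components of the null model."""

    sigma_g2: float
    sigma_pe2: float
    sigma_e2: float
    loglik: float  # restricted log-likelihood up to an additive constant
    excluded_chrom: int | None = None
    converged: bool = True

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sigma_g2, self.sigma_pe2, self.sigma_e2)


@dataclass
class SnpAssocRecord:
    """Joint per-SNP estimates of the origin and residual allele effects."""

    snp_id: str
    origin_effect: float
    origin_se: float
    origin_p: float
    allele_effect: float
    allele_se: float
    allele_p: float
    origin_estimable: bool = True
    allele_estimable: bool = True


# --------------------------------------------------------------------------
# collapse of repeated records to animal level
# --------------------------------------------------------------------------


class _Collapsed:
    """Animal means, record counts and the within-animal sum of squares."""

    def __init__(self, pheno: PhenotypeTable, grm: GRM):
        animals = pheno.animals()
        missing = set(animals) - set(grm.samples)
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped animals absent from the GRM"
            )
        self.animals = animals
        self.grm = grm.subset(animals)
        lut = {a: i for i, a in enumerate(animals)}
        idx = np.array([lut[a] for a in pheno.animal])
        self.m = len(animals)
        self.N = pheno.n_records
        self.counts = np.bincount(idx, minlength=self.m).astype(float)
        sums = np.bincount(idx, weights=pheno.value, minlength=self.m)
        self.ybar = sums / self.counts
        self.ssw = float(np.sum((pheno.value - self.ybar[idx]) ** 2))


def _neg2_rll(
    theta_log: np.ndarray,
    G: np.ndarray,
    ybar: np.ndarray,
    ninv: np.ndarray,
    X: np.ndarray,
    N: int,
    m: int,
    ssw: float,
) -> float:
    sg2, spe2, se2 = np.exp(theta_log)
    sigma = sg2 * G + np.diag(spe2 + se2 * ninv)
    try:
        c, low = linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    si_y = linalg.cho_solve((c, low), ybar)
    si_x = linalg.cho_solve((c, low), X)
    xtsx = X.T @ si_x
    sign, logdet_x = np.linalg.slogdet(xtsx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtsx, X.T @ si_y)
    r = ybar - X @ beta
    quad = float(r @ linalg.cho_solve((c, low), r))
    within = (N - m) * np.log(se2) + ssw / se2 if N > m else 0.0
    return within + logdet + logdet_x + quad


def fit_reml(
    pheno: PhenotypeTable,
    grm: GRM,
    X: np.ndarray | None = None,
    tol: float = 1e-8,
    max_restarts: int = 3,
) -> tuple[VarianceComponents, np.ndarray, np.ndarray]:
    """REML fit of the repeated-records mixed model with fixed effects ``X``.

    ``X`` is an animal-level design (one row per animal in the phenotype
    table's animal order); ``None`` means intercept only.  Returns the
    variance components together with the GLS fixed-effect estimates and
    their standard errors at the REML optimum.

    Components are optimized on the log scale; an estimate pinned at the
    lower bound (1e-8 of the phenotypic variance) is reported clipped with
    a warning.
    """
    col = _Collapsed(pheno, grm)
    G = col.grm.matrix
    ninv = 1.0 / col.counts
    if X is None:
        X = np.ones((col.m, 1))
    X = np.asarray(X, dtype=float)
    if X.shape[0] != col.m:
        raise ValueError("fixed-effect design must have one row per animal")

    vary = float(np.var(col.ybar)) + 1e-12
    floor = 1e-8 * vary
    args = (G, col.ybar, ninv, X, col.N, col.m, col.ssw)

    if col.N > col.m:
        se0 = max(col.ssw / (col.N - col.m), floor)
    else:
        se0 = vary / 3
    starts = [
        np.log([max(vary / 3, floor), max(vary / 6, floor), se0]),
        np.log([max(vary, floor), floor * 10, se0]),
        np.log([floor * 10, max(vary / 2, floor), se0]),
    ]
    trace: list = []
    best = None
    for x0 in starts[:max_restarts]:
        res = optimize.minimize(
            _neg2_rll,
            x0,
            args=args,
            method="L-BFGS-B",
            bounds=[(np.log(floor), np.log(vary * 1e4))] * 3,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        trace.append((x0.tolist(), res.fun, res.success))
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success and best is res:
            break
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("REML did not converge", trace)
    # polish with a derivative-free pass; helps when L-BFGS-B stalls early
    res = optimize.minimize(
        _neg2_rll, best.x, args=args, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": tol, "maxiter": 2000},
    )
    if res.fun <= best.fun:
        best = res
    theta = np.exp(best.x)
    if np.any(theta <= floor * 1.01):
        warnings.warn(
            "a variance component was clipped at its lower bound", stacklevel=2
        )
    vc = VarianceComponents(
        sigma_g2=float(theta[0]),
        sigma_pe2=float(theta[1]),
        sigma_e2=float(theta[2]),
        loglik=-0.5 * float(best.fun),
        excluded_chrom=grm.excluded_chrom,
        converged=True,
    )
    # GLS estimates at the optimum
    sigma = theta[0] * G + np.diag(theta[1] + theta[2] * ninv)
    c, low = linalg.cho_factor(sigma, lower=True)
    si_x = linalg.cho_solve((c, low), X)
    xtsx = X.T @ si_x
    cov = np.linalg.inv(xtsx)
    beta = cov @ (si_x.T @ col.ybar)
    se = np.sqrt(np.diag(cov))
    return vc, beta, se


def fit_null_reml(
    pheno: PhenotypeTable, grm: GRM, tol: float = 1e-8
) -> VarianceComponents:
    """Intercept-only REML fit; the first stage of the EMMAX scan."""
    vc, _, _ = fit_reml(pheno, grm, X=None, tol=tol)
    return vc


# --------------------------------------------------------------------------
# per-SNP GLS at fixed variance components
# --------------------------------------------------------------------------


def _wald(beta: float, se: float) -> tuple[float, float]:
    """Two-sided Wald p and -log10 p from chi-square with 1 df."""
    stat = (beta / se) ** 2
    p = float(stats.chi2.sf(stat, df=1))
    neglog = float(-stats.chi2.logsf(stat, df=1) / LOG10)
    return p, neglog


class SnpTester:
    """Per-SNP GLS machinery with the variance structure fixed at ``vc``.

    Precomputes the inverse covariance of animal means so each SNP test
    costs a handful of length-m dot products.
    """

    def __init__(self, pheno: PhenotypeTable, grm: GRM, vc: VarianceComponents):
        col = _Collapsed(pheno, grm)
        self.animals = col.animals
        self.vc = vc
        sigma = vc.sigma_g2 * col.grm.matrix + np.diag(
            vc.sigma_pe2 + vc.sigma_e2 / col.counts
        )
        self.sigma_inv = np.linalg.inv(sigma)
        self.ybar = col.ybar
        self.one = np.ones(col.m)
        self.si_one = self.sigma_inv @ self.one
        self.si_y = self.sigma_inv @ self.ybar
        self.oo = float(self.one @ self.si_one)
        self.oy = float(self.one @ self.si_y)

    def test(
        self,
        origin_dosage: np.ndarray,
        allele_dosage: np.ndarray,
        snp_id: str = "",
    ) -> SnpAssocRecord:
        """Jointly estimate and test the origin and residual allele effects.

        A design column that is constant in the sample (or collinear with
        the others) makes its effect non-estimable; it is flagged and the
        remaining effect is still returned.
        """
        xo = np.asarray(origin_dosage, dtype=float)
        xa = np.asarray(allele_dosage, dtype=float)
        use_o = bool(np.ptp(xo) > 0)
        use_a = bool(np.ptp(xa) > 0)
        if use_o and use_a:
            rec = self._gls([xo, xa], snp_id, (True, True))
            if rec is not None:
                return rec
            use_a = False  # collinear pair: origin keeps, residual dropped
        if use_o and not use_a:
            rec = self._gls([xo], snp_id, (True, False))
            if rec is not None:
                return rec
            use_o = False
        if use_a and not use_o:
            rec = self._gls([xa], snp_id, (False, True))
            if rec is not None:
                return rec
            use_a = False
        return SnpAssocRecord(
            snp_id, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, False
        )

    def _gls(
        self, cols: list[np.ndarray], snp_id: str, which: tuple[bool, bool]
    ) -> SnpAssocRecord | None:
        si_cols = [self.sigma_inv @ c for c in cols]
        k = len(cols) + 1
        A = np.empty((k, k))
        b = np.empty(k)
        A[0, 0] = self.oo
        b[0] = self.oy
        for i, (c, sic) in enumerate(zip(cols, si_cols), start=1):
            A[0, i] = A[i, 0] = float(self.one @ sic)
            b[i] = float(c @ self.si_y)
            for j, cj in enumerate(cols[: i], start=1):
                A[i, j] = A[j, i] = float(cj @ sic)
        if np.linalg.cond(A) > 1e10:
            return None
        cov = np.linalg.inv(A)
        beta = cov @ b
        se = np.sqrt(np.diag(cov))
        out = {
            "origin": (np.nan, np.nan, np.nan),
            "allele": (np.nan, np.nan, np.nan),
        }
        names = [n for n, u in zip(("origin", "allele"), which) if u]
        for i, name in enumerate(names, start=1):
            p, _ = _wald(beta[i], se[i])
            out[name] = (float(beta[i]), float(se[i]), p)
        return SnpAssocRecord(
            snp_id,
            *out["origin"],
            *out["allele"],
            origin_estimable=which[0],
            allele_estimable=which[1],
        )


# --------------------------------------------------------------------------
# genome scan
# --------------------------------------------------------------------------


def gwa_scan(
    pheno: PhenotypeTable,
    panel: HaplotypePanel,
    ancestry: AncestryMatrix,
    attach_q: bool = True,
    reml_tol: float = 1e-8,
) -> dict[str, pd.DataFrame]:
    """Genome-wide dual-effect association scan with LOCO GRMs.

    For each chromosome the GRM is rebuilt on all other chromosomes, the
    null variance components are refit, and every SNP on the chromosome is
    tested by GLS.  Returns ``{"origin": ..., "allele": ...}`` scan frames
    with per-SNP effect, SE, p and (optionally) Storey q values.
    """
    animals = pheno.animals()
    sub_panel = panel.take_animals(animals)
    sub_anc = ancestry.take_animals(animals)
    odos_all = eut_dosage(sub_anc)
    ados_all = sub_panel.dosages().astype(float)

    rows_o: list[dict] = []
    rows_a: list[dict] = []
    for c, sl in sub_panel.iter_chromosomes():
        grm = build_grm(sub_panel, exclude_chrom=c)
        vc = fit_null_reml(pheno, grm, tol=reml_tol)
        logger.info(
            "chromosome %d: REML (sg2, spe2, se2) = (%.4g, %.4g, %.4g)",
            c, vc.sigma_g2, vc.sigma_pe2, vc.sigma_e2,
        )
        tester = SnpTester(pheno, grm, vc)
        for s in range(sl.start, sl.stop):
            snp_id = f"snp_{c}_{panel.pos[s]}"
            rec = tester.test(odos_all[s], ados_all[s], snp_id)
            base = {"chrom": c, "pos": int(panel.pos[s]), "snp_id": snp_id}
            rows_o.append(
                base
                | {
                    "effect": rec.origin_effect,
                    "se": rec.origin_se,
                    "p": rec.origin_p,
                    "estimable": rec.origin_estimable,
                }
            )
            rows_a.append(
                base
                | {
                    "effect": rec.allele_effect,
                    "se": rec.allele_se,
                    "p": rec.allele_p,
                    "estimable": rec.allele_estimable,
                }
            )
    out = {}
    for name, rows in (("origin", rows_o), ("allele", rows_a)):
        df = pd.DataFrame(rows)
        with np.errstate(divide="ignore"):
            df["neglog10p"] = -np.log10(df["p"])
        if attach_q:
            from .mtc import qvalues

            ok = df["p"].notna()
            df["q"] = np.nan
            if ok.any():
                df.loc[ok, "q"] = qvalues(df.loc[ok, "p"].to_numpy()).q
        out[name] = df
    return out
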