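"""Per-probe differential methylation with empirical-Bayes moderation.

The model is the classic microarray workflow: an ordinary least-squares
linear model per probe (group + batch covariates, optionally a latent
unwanted-variation factor estimated from negative-control probes),
squeezing of the per-probe residual variances toward a common prior by
matching moments of log s^2 to a scaled-F prior predictive, moderated
t-statistics on augmented degrees of freedom, and Benjamini-Hochberg
control of the false discovery rate. Methylation is modelled on the beta
scale by default; an M-value (logit) option is available.

Presented statsmodels-style: :class:`DifferentialMethylation` is the
model object, :meth:`DifferentialMethylation.fit` returns a
:class:`DiffMethResults` carrying the per-probe table, the moderation
hyper-parameters and summary/tally helpers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, ValidationError, arm_samples

log = logging.getLogger("methregen.diffmeth")

__all__ = [
    "DesignMatrix",
    "ModerationParams",
    "DifferentialMethylation",
    "DiffMethResults",
    "build_design",
    "estimate_ruv_factor",
    "fit_probe_models",
    "moderate_variances",
    "trigamma_inverse",
    "benjamini_hochberg",
    "classify_dm",
    "tally_by_feature",
    "paired_fold_change",
]


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Full-column-rank design aligned to a beta-matrix sample order."""

    sample_ids: list[str]
    X: pd.DataFrame  # rows = samples, columns = model terms
    contrast: np.ndarray  # contrast vector over columns

    def __post_init__(self):
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.shape[1] != self.contrast.shape[0]:
            raise ValidationError("contrast length does not match design columns")
        if np.linalg.matrix_rank(self.X.to_numpy(dtype=float)) < self.X.shape[1]:
            raise ValidationError("design matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def build_design(
    sheet: pd.DataFrame,
    arm: str | None = None,
    paired: bool = True,
    include_batch: bool = True,
    ruv_factor: pd.Series | np.ndarray | None = None,
) -> DesignMatrix:
    """Design for the BaCl2-vs-PBS contrast within one study arm.

    Columns: intercept, limb indicator (the contrast), optional batch
    dummies, optional per-animal blocking dummies, optional RUV factor.
    ``paired=False`` reproduces the unpaired group+batch covariate model;
    ``paired=True`` adds animal blocks for the contralateral-limb design.
    """
    sub = arm_samples(sheet, arm) if arm is not None else sheet.reset_index(drop=True)
    if sub.empty:
        raise ValidationError(f"no samples for arm {arm!r}")
    sample_ids = sub["sample_id"].tolist()
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    cols["limb_BaCl2"] = (sub["limb"] == "BaCl2").to_numpy(dtype=float)
    if include_batch:
        batches = sorted(sub["batch"].unique())
        for b in batches[1:]:
            cols[f"batch_{b}"] = (sub["batch"] == b).to_numpy(dtype=float)
    if paired:
        animals = sorted(sub["animal_id"].unique())
        for a in animals[1:]:
            cols[f"animal_{a}"] = (sub["animal_id"] == a).to_numpy(dtype=float)
    if ruv_factor is not None:
        rv = (
            ruv_factor.reindex(sample_ids).to_numpy(dtype=float)
            if isinstance(ruv_factor, pd.Series)
            else np.asarray(ruv_factor, dtype=float)
        )
        if rv.shape[0] != len(sample_ids) or np.isnan(rv).any():
            raise ValidationError("RUV factor does not cover all design samples")
        cols["ruv_1"] = rv
    X = pd.DataFrame(cols, index=sample_ids)
    # drop collinear batch/animal dummies (e.g. batch nested within animals)
    X = _prune_collinear(X, protected=("intercept", "limb_BaCl2", "ruv_1"))
    contrast = np.zeros(X.shape[1])
    contrast[X.columns.get_loc("limb_BaCl2")] = 1.0
    return DesignMatrix(sample_ids=sample_ids, X=X, contrast=contrast)


def _prune_collinear(X: pd.DataFrame, protected: tuple[str, ...]) -> pd.DataFrame:
    keep: list[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(col)
        elif col in protected:
            raise ValidationError(f"protected design column {col!r} is collinear")
        else:
            log.info("dropping collinear design column %s", col)
    return X[keep]


# ---------------------------------------------------------------------------
# RUV factor from negative-control probes
# ---------------------------------------------------------------------------


def estimate_ruv_factor(
    beta: BetaMatrix,
    control_probes,
    design: DesignMatrix | None = None,
    k: int = 1,
) -> pd.Series:
    """Latent unwanted-variation factor from negative-control probes.

    The fitted covariate effects of ``design`` (if given) are removed
    from the control-probe submatrix, rows are centered, and the first
    right singular vector is returned (unit norm, sign fixed so the
    largest-magnitude entry is positive).

    ``design`` should contain *nuisance* covariates only (intercept,
    batch). Projecting out the biological contrast before the SVD would
    strip the factor of its component along that contrast, so including
    the estimated factor downstream would shrink residuals while leaving
    the confounding bias in the contrast coefficient untouched; control
    probes are assumed unaffected by the biology, which is what licenses
    estimating the factor without removing it.
    """
    if k != 1:
        raise NotImplementedError("only k=1 is supported")
    control_probes = [p for p in control_probes]
    if len(control_probes) < 10:
        raise ValidationError("need >=10 control probes for RUV estimation")
    Y = beta.values.loc[control_probes]
    sample_ids = list(beta.sample_ids)
    M = Y.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValidationError("control probes contain missing values")
    if design is not None:
        X = design.X.reindex(design.sample_ids).to_numpy(dtype=float)
        if design.sample_ids != sample_ids:
            raise ValidationError("design samples do not match beta matrix")
        coef, *_ = np.linalg.lstsq(X, M.T, rcond=None)
        M = M - (X @ coef).T
    M = M - M.mean(axis=1, keepdims=True)
    if not np.any(np.abs(M) > 1e-12):
        raise ValidationError("control-probe submatrix has no variation (rank 0)")
    _, s, vt = np.linalg.svd(M, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValidationError("zero leading singular value for control probes")
    v = vt[0]
    v = v / np.linalg.norm(v)
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return pd.Series(v, index=sample_ids, name="ruv_1")


# ---------------------------------------------------------------------------
# Per-probe OLS
# ---------------------------------------------------------------------------


@dataclass
class ProbeFits:
    probe_ids: list[str]
    effect: np.ndarray  # contrast estimate per probe
    coef: np.ndarray  # probes x params
    s_sq: np.ndarray  # residual variance
    df_resid: np.ndarray
    u: np.ndarray  # unscaled contrast SE factor sqrt(c' (X'X)^-1 c)


def _ols_block(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray):
    """Vectorized OLS of every row of Y on X. Returns coef, s2, df, u."""
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    if rank < p:
        raise ValidationError("design matrix is rank deficient")
    resid = Y.T - X @ coef
    df = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    rss[rss < 1e-24] = 0.0  # exact fits leave O(eps^2) numerical residue
    s2 = rss / df if df > 0 else np.full(Y.shape[0], np.nan)
    xtx_inv = np.linalg.inv(X.T @ X)
    u = math.sqrt(float(contrast @ xtx_inv @ contrast))
    return coef.T, s2, df, u


def fit_probe_models(beta: BetaMatrix, design: DesignMatrix) -> ProbeFits:
    """Ordinary least squares for every probe against a shared design.

    Probes with missing values are refitted on their observed subset with
    recomputed residual df and contrast SE factor.
    """
    Y = beta.values.reindex(columns=design.sample_ids).to_numpy(dtype=float)
    X = design.X.to_numpy(dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise ValidationError(f"no residual df: {n} samples, {p} parameters")
    probe_ids = list(beta.probe_ids)
    complete = ~np.isnan(Y).any(axis=1)

    coef = np.full((Y.shape[0], p), np.nan)
    s2 = np.full(Y.shape[0], np.nan)
    dfr = np.zeros(Y.shape[0])
    u = np.full(Y.shape[0], np.nan)

    if complete.any():
        c_coef, c_s2, c_df, c_u = _ols_block(Y[complete], X, design.contrast)
        coef[complete] = c_coef
        s2[complete] = c_s2
        dfr[complete] = c_df
        u[complete] = c_u

    for i in np.flatnonzero(~complete):
        obs = ~np.isnan(Y[i])
        Xi = X[obs]
        if Xi.shape[0] - p < 1 or np.linalg.matrix_rank(Xi) < p:
            log.warning("probe %s: too many missing values to fit; skipped", probe_ids[i])
            continue
        ci, s2i, dfi, ui = _ols_block(Y[i, obs][None, :], Xi, design.contrast)
        coef[i] = ci[0]
        s2[i] = s2i[0]
        dfr[i] = dfi
        u[i] = ui

    effect = coef @ design.contrast
    n_zero = int(np.sum(s2 == 0))
    if n_zero:
        log.info("%d probe(s) with zero residual variance", n_zero)
    return ProbeFits(probe_ids=probe_ids, effect=effect, coef=coef, s_sq=s2, df_resid=dfr, u=u)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation (Smyth 2004 moment matching)
# ---------------------------------------------------------------------------


@dataclass
class ModerationParams:
    """Prior df and variance of the scaled inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom; may be +inf
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValidationError("require d0 > 0 and s0_sq > 0")


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            return x
    raise RuntimeError("trigamma inversion did not converge")


def moderate_variances(
    s_sq: np.ndarray, df: np.ndarray
) -> tuple[ModerationParams, np.ndarray]:
    """Estimate (d0, s0^2) and squeeze per-probe variances toward the prior.

    Matches the first two moments of log s_g^2 to the scaled-F prior
    predictive via digamma/trigamma inversion; the posterior variance is
    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g). Non-convergence of the
    trigamma inversion falls back to d0 = +inf (fully pooled), logged.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0) & (df > 0)
    if ok.sum() < 30:
        raise ValidationError("need >=30 probes with positive residual variance")
    z = np.log(s_sq[ok])
    dg = df[ok]
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = float(e.mean())
    n = e.size
    target = float(np.mean((e - emean) ** 2 * n / (n - 1) - special.polygamma(1, dg / 2.0)))
    if target > 0:
        try:
            d0 = 2.0 * trigamma_inverse(target)
            s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        except RuntimeError:
            log.warning("trigamma inversion failed; falling back to d0 = +inf")
            d0, s0_sq = math.inf, float(np.average(s_sq[ok], weights=df[ok]))
    else:
        # no excess spread in log s^2: fully pooled (df-weighted) variance
        d0, s0_sq = math.inf, float(np.average(s_sq[ok], weights=df[ok]))
    params = ModerationParams(d0=d0, s0_sq=s0_sq)
    post = posterior_variances(s_sq, df, params)
    return params, post


def posterior_variances(s_sq: np.ndarray, df: np.ndarray, params: ModerationParams) -> np.ndarray:
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    if math.isinf(params.d0):
        return np.full_like(s_sq, params.s0_sq)
    return (params.d0 * params.s0_sq + df * s_sq) / (params.d0 + df)


def moderated_t(
    fits: ProbeFits, params: ModerationParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, ModerationParams | None]:
    """Moderated (or ordinary, if ``params`` is None-moderation) t and p."""
    if params is None:
        post = fits.s_sq
        df_total = fits.df_resid
    else:
        post = posterior_variances(fits.s_sq, fits.df_resid, params)
        df_total = fits.df_resid + params.d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.effect / (fits.u * np.sqrt(post))
    p = np.full_like(t, np.nan)
    finite_df = np.isfinite(df_total) & (df_total > 0)
    tt = np.where(np.isfinite(t), t, 0.0)
    p[finite_df & np.isfinite(t)] = 2.0 * stats.t.sf(
        np.abs(tt[finite_df & np.isfinite(t)]), df_total[finite_df & np.isfinite(t)]
    )
    inf_df = np.isinf(df_total) & np.isfinite(t)
    p[inf_df] = 2.0 * stats.norm.sf(np.abs(tt[inf_df]))
    return t, p, post, params


# ---------------------------------------------------------------------------
# BH correction / classification / tallies
# ---------------------------------------------------------------------------


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def classify_dm(
    table: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Assign hypo/hyper/ns direction labels (effect = BaCl2 - PBS)."""
    table = table.copy()
    sig = table["q"] < q_threshold
    direction = np.where(
        sig & (table["effect"] < 0),
        "hypo",
        np.where(sig & (table["effect"] > 0), "hyper", "ns"),
    )
    zero_sig = sig & (table["effect"] == 0)
    if zero_sig.any():
        log.warning("%d significant probe(s) with zero effect classified ns", zero_sig.sum())
    table["direction"] = direction
    return table


def tally_by_feature(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of hypo/hyper significant probes per feature class."""
    from .io import FEATURE_CLASSES

    sig = table[table["direction"].isin(["hypo", "hyper"])]
    counts = (
        sig.groupby(["feature_class", "direction"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(FEATURE_CLASSES, fill_value=0)
        .reindex(columns=["hypo", "hyper"], fill_value=0)
    )
    counts.index.name = "feature_class"
    return counts


def promoter_gene_table(table: pd.DataFrame) -> pd.DataFrame:
    sig = table[(table["direction"] != "ns") & (table["feature_class"] == "promoter")]
    return (
        sig.groupby(["gene_id", "direction"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["hypo", "hyper"], fill_value=0)
        .reset_index()
    )


def paired_fold_change(
    beta: BetaMatrix, sheet: pd.DataFrame, probe_id: str
) -> tuple[pd.Series, float]:
    """Per-animal BaCl2/PBS beta ratios for one probe and their geometric mean."""
    row = beta.values.loc[probe_id]
    wide = sheet.pivot(index="animal_id", columns="limb", values="sample_id")
    ratios = {}
    for animal, limbs in wide.iterrows():
        if pd.isna(limbs.get("PBS")) or pd.isna(limbs.get("BaCl2")):
            continue
        pbs = row.get(limbs["PBS"], np.nan)
        bacl2 = row.get(limbs["BaCl2"], np.nan)
        if np.isnan(pbs) or np.isnan(bacl2):
            continue
        if pbs == 0:
            log.warning("probe %s: animal %s has PBS beta 0; skipped", probe_id, animal)
            continue
        ratios[animal] = bacl2 / pbs
    series = pd.Series(ratios, name=probe_id, dtype=float)
    if series.empty:
        raise ValidationError(f"probe {probe_id}: no animals with both limbs")
    gmean = float(np.exp(np.mean(np.log(series.to_numpy()))))
    return series, gmean


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


def _to_m_values(values: pd.DataFrame, eps: float = 1e-3) -> pd.DataFrame:
    clipped = values.clip(lower=eps, upper=1 - eps)
    return np.log2(clipped / (1 - clipped))


class DifferentialMethylation:
    """Per-probe linear model of methylation against a study design.

    Parameters
    ----------
    beta
        Probes x samples methylation matrix.
    design
        Design with the BaCl2-vs-PBS contrast (see :func:`build_design`).
    manifest
        Optional probe manifest supplying feature_class/gene_id for the
        result table.
    use_m_values
        Model logit-transformed betas (M-values) instead of betas.
    """

    def __init__(
        self,
        beta: BetaMatrix,
        design: DesignMatrix,
        manifest: pd.DataFrame | None = None,
        use_m_values: bool = False,
    ):
        missing = [s for s in design.sample_ids if s not in set(beta.sample_ids)]
        if missing:
            raise ValidationError(f"design samples absent from beta matrix: {missing[:5]}")
        self.beta = beta
        self.design = design
        self.manifest = manifest
        self.use_m_values = use_m_values

    @classmethod
    def from_study(
        cls,
        beta: BetaMatrix,
        sheet: pd.DataFrame,
        arm: str,
        manifest: pd.DataFrame | None = None,
        paired: bool = True,
        include_batch: bool = True,
        ruv: bool | pd.Series = False,
        control_probes=None,
        use_m_values: bool = False,
    ) -> "DifferentialMethylation":
        """Build the model for one arm's BaCl2-vs-PBS contrast.

        ``ruv=True`` estimates one latent factor from ``control_probes``
        (or, if none given, from the 1% least-variable probes after
        removing the known-covariate fit).
        """
        design = build_design(sheet, arm=arm, paired=paired, include_batch=include_batch)
        sub = beta.subset_samples(design.sample_ids)
        if isinstance(ruv, pd.Series):
            factor = ruv
        elif ruv:
            nuisance = _nuisance_design(sheet, arm, include_batch=include_batch)
            if control_probes is None:
                control_probes = _default_control_probes(sub, nuisance)
            factor = estimate_ruv_factor(sub, control_probes, design=nuisance)
        else:
            factor = None
        if factor is not None:
            design = build_design(
                sheet, arm=arm, paired=paired, include_batch=include_batch, ruv_factor=factor
            )
        return cls(sub, design, manifest=manifest, use_m_values=use_m_values)

    def fit(self, moderate: bool = True) -> "DiffMethResults":
        values = self.beta.values.reindex(columns=self.design.sample_ids)
        if self.use_m_values:
            values = _to_m_values(values)
        # M-values fall outside [0,1], so bypass BetaMatrix validation
        mat = BetaMatrix.__new__(BetaMatrix)
        mat.values = values
        fits = fit_probe_models(mat, self.design)
        if moderate:
            params, _ = moderate_variances(fits.s_sq, fits.df_resid)
        else:
            params = None
        t, p, post, params = moderated_t(fits, params)
        q = benjamini_hochberg(p)
        table = pd.DataFrame(
            {
                "probe_id": fits.probe_ids,
                "effect": fits.effect,
                "t_mod": t,
                "p": p,
                "q": q,
                "s_sq": fits.s_sq,
                "df_resid": fits.df_resid,
            }
        )
        if self.manifest is not None:
            ann = self.manifest.set_index("probe_id")[["feature_class", "gene_id", "chrom", "pos"]]
            table = table.join(ann, on="probe_id")
        else:
            table["feature_class"] = "intergenic"
            table["gene_id"] = pd.NA
        return DiffMethResults(model=self, fits=fits, params=params, table=table)


@dataclass
class DiffMethResults:
    """Fitted per-probe differential-methylation results."""

    model: DifferentialMethylation
    fits: ProbeFits
    params: ModerationParams | None
    table: pd.DataFrame
    q_threshold: float = 0.05
    _classified: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def records(self) -> pd.DataFrame:
        """DM record table with hypo/hyper/ns direction labels."""
        if self._classified is None:
            self._classified = classify_dm(self.table, self.q_threshold)
        return self._classified

    def classify(self, q_threshold: float = 0.05) -> pd.DataFrame:
        self.q_threshold = q_threshold
        self._classified = classify_dm(self.table, q_threshold)
        return self._classified

    def tally_by_feature(self) -> pd.DataFrame:
        return tally_by_feature(self.records)

    def paired_fold_change(self, sheet: pd.DataFrame, probe_id: str):
        return paired_fold_change(self.model.beta, sheet, probe_id)

    def summary(self) -> str:
        rec = self.records
        n_sig = int((rec["direction"] != "ns").sum())
        lines = [
            "Differential methylation (moderated t)",
            "=" * 42,
            f"probes:            {len(rec)}",
            f"samples:           {self.model.design.n_samples}",
            f"design columns:    {self.model.design.n_params}",
            f"scale:             {'M-values' if self.model.use_m_values else 'beta'}",
        ]
        if self.params is not None:
            d0 = "inf" if math.isinf(self.params.d0) else f"{self.params.d0:.3f}"
            lines += [f"prior df (d0):     {d0}", f"prior var (s0^2):  {self.params.s0_sq:.5g}"]
        lines += [
            f"q < {self.q_threshold:g}:          {n_sig}"
            f" ({int((rec['direction'] == 'hypo').sum())} hypo,"
            f" {int((rec['direction'] == 'hyper').sum())} hyper)",
        ]
        return "\n".join(lines)


def _nuisance_design(sheet: pd.DataFrame, arm: str | None, include_batch: bool = True) -> DesignMatrix:
    """Intercept + batch dummies only, for RUV factor estimation."""
    sub = arm_samples(sheet, arm) if arm is not None else sheet.reset_index(drop=True)
    sample_ids = sub["sample_id"].tolist()
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    if include_batch:
        for b in sorted(sub["batch"].unique())[1:]:
            cols[f"batch_{b}"] = (sub["batch"] == b).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=sample_ids)
    contrast = np.zeros(X.shape[1])
    contrast[0] = 1.0
    return DesignMatrix(sample_ids=sample_ids, X=X, contrast=contrast)


def _default_control_probes(beta: BetaMatrix, design: DesignMatrix) -> list[str]:
    """1% least-variable probes after removing the known-covariate fit."""
    Y = beta.values.reindex(columns=design.sample_ids).to_numpy(dtype=float)
    complete = ~np.isnan(Y).any(axis=1)
    X = design.X.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y[complete].T, rcond=None)
    resid = Y[complete].T - X @ coef
    rvar = resid.var(axis=0)
    ids = np.asarray(list(beta.probe_ids))[complete]
    n_ctrl = max(10, int(0.01 * len(ids)))
    order = np.argsort(rvar, kind="stable")
    return ids[order[:n_ctrl]].tolist()
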