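"""Empirical-Bayes moderated t-tests and interactome classification.

Each Cav1 condition (NT, HYPO, REC) is contrasted against the NES
cytoplasmic spatial reference with a two-group moderated t-test: the
per-protein pooled residual variance s_g^2 (d_g = n1 + n2 - 2 df) is
shrunk toward an empirical-Bayes prior (d0, s0^2),

    s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),
    t_mod    = logFC / sqrt(s_post^2 * (1/n1 + 1/n2)),

with a two-sided p-value on d0 + d_g degrees of freedom. The prior is
estimated by matching the mean and spread of log s_g^2 to the
theoretical scaled-F marginal (digamma/trigamma moment method).

Significant proteins (p < 0.05 and logFC > 0 by default) are then
partitioned into the 2^3 NT/HYPO/REC membership categories; proteins
enriched in both NT and REC but not HYPO constitute the
tension-sensitive ("co-recovered") interactome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .proteomics import ConfigError, InputError, LogMatrix, SampleDesign

D0_INF = 1e6  # documented cap representing an infinite prior df

CATEGORIES = (
    "NT_only",
    "HYPO_only",
    "REC_only",
    "NT&HYPO",
    "NT&REC",
    "HYPO&REC",
    "NT&HYPO&REC",
    "none",
)


class EstimationError(RuntimeError):
    """Too little data to estimate the variance prior."""


@dataclass(frozen=True)
class VariancePrior:
    """Shrinkage hyperparameters: prior df d0 (capped at 1e6 for
    infinity) and prior variance s0_sq in log2^2 units."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.s0_sq <= 0:
            raise ConfigError("require d0 > 0 and s0_sq > 0")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y by Newton iteration on the monotone map."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    # asymptotic starting value trigamma(x) ~ 1/x for large x
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(
    s_g_sq: np.ndarray | pd.Series, d_g: np.ndarray | pd.Series | float
) -> VariancePrior:
    """Estimate (d0, s0^2) from observed residual variances.

    Under the hierarchical model, s_g^2 | sigma_g^2 is scaled chi^2
    with d_g df and sigma_g^2 follows a scaled inverse chi^2 prior, so
    log s_g^2 has a known scaled-log-F marginal. Matching its mean and
    variance through digamma/trigamma identities yields the moment
    estimates. When the observed spread of log-variances does not
    exceed the chi^2 sampling spread, d0 is infinite (capped at 1e6).
    """
    s2 = np.asarray(s_g_sq, dtype=float)
    d = np.broadcast_to(np.asarray(d_g, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (d >= 1)
    s2, d = s2[ok], d[ok]
    if len(s2) < 30:
        raise EstimationError(
            f"only {len(s2)} usable variances; need >= 30 to fit the prior"
        )
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_mean = e.mean()
    n = len(e)
    e_var = np.sum((e - e_mean) ** 2) / (n - 1) - np.mean(special.polygamma(1, d / 2))
    if e_var > 0:
        d0 = 2 * _trigamma_inverse(e_var)
        d0 = min(d0, D0_INF)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0 = D0_INF
        s0_sq = np.exp(e_mean)
    return VariancePrior(float(d0), float(s0_sq))


def fit_variance_prior_from_logmat(
    logmat: LogMatrix,
    contrast: tuple[tuple[str, str], tuple[str, str]],
) -> VariancePrior:
    """Prior fit on the pooled two-group residual variances of a contrast."""
    s2, d = _pooled_variances(logmat, contrast)
    return fit_variance_prior(s2[d >= 1], d[d >= 1])


def _group_values(logmat: LogMatrix, bait: str, condition: str) -> pd.DataFrame:
    samples = logmat.design.group_samples(bait, condition)
    return logmat.values[samples]


def _pooled_variances(
    logmat: LogMatrix, contrast: tuple[tuple[str, str], tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    (b1, c1), (b2, c2) = contrast
    g1 = _group_values(logmat, b1, c1).to_numpy(float)
    g2 = _group_values(logmat, b2, c2).to_numpy(float)
    n1 = np.sum(~np.isnan(g1), axis=1)
    n2 = np.sum(~np.isnan(g2), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v1 = np.nanvar(g1, axis=1, ddof=1)
        v2 = np.nanvar(g2, axis=1, ddof=1)
    d_g = n1 + n2 - 2.0
    ss = np.where(n1 > 1, (n1 - 1) * v1, 0.0) + np.where(n2 > 1, (n2 - 1) * v2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_g_sq = np.where(d_g > 0, ss / np.where(d_g > 0, d_g, 1.0), np.nan)
    return s_g_sq, d_g


def moderated_t_test(
    logmat: LogMatrix,
    contrast: tuple[tuple[str, str], tuple[str, str]],
    prior: VariancePrior | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test for one contrast.

    ``contrast`` names ((bait1, cond1), (bait2, cond2)); logFC is
    group1 mean minus group2 mean on the log2 scale. Proteins with
    fewer than 2 present values in either group are marked
    ``testable = False`` and keep NaN statistics — never silently
    dropped. ``d0_override = 0`` reduces to the ordinary pooled
    two-sample t-test.

    Returns a frame indexed by protein id with columns logFC, s_g_sq,
    d_g, s_post_sq, t_mod, p, testable.
    """
    design = logmat.design
    for bait, cond in contrast:
        design.group_samples(bait, cond)  # raises InputError if unknown

    (b1, c1), (b2, c2) = contrast
    g1 = _group_values(logmat, b1, c1).to_numpy(float)
    g2 = _group_values(logmat, b2, c2).to_numpy(float)
    n1 = np.sum(~np.isnan(g1), axis=1).astype(float)
    n2 = np.sum(~np.isnan(g2), axis=1).astype(float)
    testable = (n1 >= 2) & (n2 >= 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        logfc = np.nanmean(g1, axis=1) - np.nanmean(g2, axis=1)
    s_g_sq, d_g = _pooled_variances(logmat, contrast)

    if prior is None:
        prior = fit_variance_prior(s_g_sq[testable], d_g[testable])
    d0 = prior.d0 if d0_override is None else float(d0_override)

    if d0 == 0:
        s_post_sq = s_g_sq
        df_total = d_g
    elif d0 >= D0_INF:
        s_post_sq = np.full_like(s_g_sq, prior.s0_sq)
        df_total = np.minimum(d0 + d_g, D0_INF)
    else:
        s_post_sq = (d0 * prior.s0_sq + d_g * s_g_sq) / (d0 + d_g)
        df_total = d0 + d_g

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s_post_sq * (1.0 / n1 + 1.0 / n2))
        t_mod = logfc / se
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "s_g_sq": s_g_sq,
            "d_g": d_g,
            "s_post_sq": s_post_sq,
            "t_mod": t_mod,
            "p": p,
            "testable": testable,
        },
        index=logmat.protein_ids,
    )
    out.loc[~testable, ["logFC", "s_g_sq", "s_post_sq", "t_mod", "p"]] = np.nan
    return out


def nes_contrasts(
    logmat: LogMatrix,
    prior: VariancePrior | None = None,
) -> dict[str, pd.DataFrame]:
    """Each Cav1 condition vs the NES-NT spatial reference.

    A single prior (fit on the pooled variances of all three
    contrasts) is shared across conditions unless one is supplied.
    """
    conditions = sorted(
        {c for b, c in logmat.design.groups() if b == "Cav1"},
        key=["NT", "HYPO", "REC"].index,
    )
    if prior is None:
        s2_all, d_all = [], []
        for cond in conditions:
            s2, d = _pooled_variances(logmat, (("Cav1", cond), ("NES", "NT")))
            ok = d >= 1
            s2_all.append(s2[ok])
            d_all.append(d[ok])
        prior = fit_variance_prior(np.concatenate(s2_all), np.concatenate(d_all))
    return {
        cond: moderated_t_test(logmat, (("Cav1", cond), ("NES", "NT")), prior)
        for cond in conditions
    }


def call_enrichment(
    results: Mapping[str, pd.DataFrame],
    p_thresh: float = 0.05,
    lfc_thresh: float = 0.0,
) -> pd.DataFrame:
    """Boolean enrichment calls per condition vs NES.

    call = testable AND p < p_thresh AND logFC > lfc_thresh (strict
    inequalities, matching the volcano-plot criterion "p-value < 0.05
    and logFC > 0").
    """
    conds = list(results)
    universe = results[conds[0]].index
    for cond in conds[1:]:
        if not results[cond].index.equals(universe):
            raise InputError("mismatched protein universes across contrasts")
    calls = pd.DataFrame(index=universe)
    for cond, res in results.items():
        calls[cond] = (
            res["testable"]
            & (res["p"] < p_thresh)
            & (res["logFC"] > lfc_thresh)
        ).fillna(False)
    return calls


def classify_interactome(
    calls: pd.DataFrame,
) -> tuple[pd.Series, dict[str, int]]:
    """Partition proteins into the 2^3 NT/HYPO/REC membership categories.

    Returns (per-protein category series, summary counts). The summary
    additionally reports ``total_significant`` (the unique significant
    union) and ``co_recovered`` — proteins enriched in both NT and REC
    (NT&REC plus the triple), the tension-sensitive interactome.
    """
    for cond in ("NT", "HYPO", "REC"):
        if cond not in calls.columns:
            raise InputError(f"calls missing condition {cond}")
    nt = calls["NT"].to_numpy(bool)
    hy = calls["HYPO"].to_numpy(bool)
    re_ = calls["REC"].to_numpy(bool)

    # explicit truth table keyed by (NT, HYPO, REC)
    table = {
        (False, False, False): "none",
        (True, False, False): "NT_only",
        (False, True, False): "HYPO_only",
        (False, False, True): "REC_only",
        (True, True, False): "NT&HYPO",
        (True, False, True): "NT&REC",
        (False, True, True): "HYPO&REC",
        (True, True, True): "NT&HYPO&REC",
    }
    cats = pd.Series(
        [table[(a, b, c)] for a, b, c in zip(nt, hy, re_)],
        index=calls.index,
        name="category",
    )
    counts = {cat: int((cats == cat).sum()) for cat in CATEGORIES}
    counts["total_significant"] = int((cats != "none").sum())
    counts["co_recovered"] = counts["NT&REC"] + counts["NT&HYPO&REC"]
    return cats, counts


def zscore_profiles(
    logmat: LogMatrix,
    protein_subset: Iterable[str] | None = None,
    mode: Literal["per_sample", "per_condition_mean"] = "per_sample",
    bait: str = "Cav1",
) -> pd.DataFrame:
    """Row-wise z-scores of log2 intensities across the bait's samples.

    ``per_condition_mean`` first averages replicates within each
    condition. z = (x - row mean) / row sd over non-missing entries
    (sample sd, ddof=1); rows with < 2 distinct present values are
    left entirely NaN (undefined).
    """
    if mode not in ("per_sample", "per_condition_mean"):
        raise ConfigError(f"unknown mode {mode!r}")
    groups = {
        cond: samples
        for (b, cond), samples in logmat.design.groups().items()
        if b == bait
    }
    if mode == "per_sample":
        cols = [s for samples in groups.values() for s in samples]
        mat = logmat.values[cols]
    else:
        mat = pd.DataFrame(
            {cond: logmat.values[samples].mean(axis=1) for cond, samples in groups.items()}
        )
    if protein_subset is not None:
        mat = mat.loc[list(protein_subset)]
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    n_distinct = mat.apply(lambda r: r.dropna().nunique(), axis=1)
    z = mat.sub(mean, axis=0).div(sd, axis=0)
    z[(n_distinct < 2) | (sd == 0)] = np.nan
    return z


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise InputError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
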