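"""Additive linear-model cis-eQTL testing across quantification levels.

Each feature's phenotype (RPKM/RPM value, or transcript proportion) is
regressed on minor-allele dosage with optional fixed-effect covariates:

    y = mu + beta * g + C gamma + eps

and beta is tested with a two-sided t-test on the residual degrees of
freedom.  Conditional analysis re-tests one SNP with another SNP's dosage
appended as a covariate, the standard way to separate an LD proxy from an
independent signal.  A direction-of-effect summary compares the fitted
signs across levels to an expected pattern (for the packaged cassette-exon
model: inclusion junctions and cassette splice sites up, skipping junction,
skipped-transcript and flanking introns down, total gene flat).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

LEVELS = ("gene", "transcript", "exon", "junction", "splice_site", "intron")

_P_FLOOR = np.finfo(float).tiny  # reported when a fit is numerically perfect


@dataclass
class EqtlResult:
    feature_id: str
    level: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    status: str = "ok"  # "ok" | "untestable" | "collinear"

    @property
    def testable(self) -> bool:
        return self.status == "ok"


@dataclass
class DirectionReport:
    """Per-feature concordance of fitted effect signs with an expectation."""

    table: pd.DataFrame  # expected, beta, p, observed_sign, match
    n_match: int
    n_total: int

    @property
    def concordance(self) -> float:
        return self.n_match / self.n_total


def _align(
    y, g, covariates: Optional[pd.DataFrame]
) -> tuple[np.ndarray, np.ndarray, Optional[pd.DataFrame]]:
    y = pd.Series(y, dtype=float)
    g = pd.Series(g, dtype=float)
    if not y.index.equals(g.index):
        common = y.index.intersection(g.index)
        y, g = y.loc[common], g.loc[common]
    if covariates is not None:
        covariates = pd.DataFrame(covariates).astype(float)
        common = y.index.intersection(covariates.index)
        y, g, covariates = y.loc[common], g.loc[common], covariates.loc[common]
    keep = y.notna() & g.notna()
    if covariates is not None:
        keep &= covariates.notna().all(axis=1)
        covariates = covariates.loc[keep]
    return y.loc[keep], g.loc[keep], covariates


def fit_eqtl(
    y,
    g,
    covariates: Optional[pd.DataFrame] = None,
    *,
    feature_id: str = "feature",
    level: str = "gene",
    log1p: bool = False,
) -> EqtlResult:
    """OLS eQTL fit of one feature against minor-allele dosage.

    Missing values are handled by listwise deletion.  A genotype that is
    constant after filtering is flagged ``untestable`` (not an error: it is
    a data property).  Rank-deficient covariates raise a ValueError naming
    the offending column.  ``log1p`` analyzes log(1 + y).
    """
    y, g, covariates = _align(y, g, covariates)
    observed = set(np.unique(g))
    if log1p:
        y = np.log1p(y)
    n = len(y)
    k = 0 if covariates is None else covariates.shape[1]
    if len(observed) < 2:
        return EqtlResult(feature_id, level, np.nan, np.nan, np.nan, np.nan, n,
                          status="untestable")
    if n < k + 3:
        raise ValueError(
            f"{feature_id}: {n} complete cases, need >= {k + 3}"
        )
    X = pd.DataFrame({"const": 1.0, "dosage": g})
    if covariates is not None:
        base_rank = 2
        for col in covariates.columns:
            trial = np.column_stack([X.to_numpy(), covariates[col].to_numpy()])
            if np.linalg.matrix_rank(trial) <= base_rank:
                raise ValueError(
                    f"covariate column {col!r} is collinear with the design"
                )
            X[str(col)] = covariates[col].to_numpy()
            base_rank += 1
    fit = sm.OLS(np.asarray(y), X.to_numpy()).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se if se > 0 else np.sign(beta) * np.inf
    p = float(fit.pvalues[1])
    if not np.isfinite(p) or p <= 0:
        p = _P_FLOOR
    return EqtlResult(feature_id, level, beta, se, float(t), p, n)


def conditional_eqtl(
    y,
    g_test,
    g_condition,
    covariates: Optional[pd.DataFrame] = None,
    *,
    feature_id: str = "feature",
    level: str = "gene",
    log1p: bool = False,
) -> EqtlResult:
    """Test ``g_test`` while conditioning on ``g_condition`` as a covariate.

    If the two dosage vectors are essentially collinear (|r| > 0.999 on
    shared complete cases) the result is flagged instead of fitted."""
    g_test = pd.Series(g_test, dtype=float)
    g_condition = pd.Series(g_condition, dtype=float)
    common = g_test.index.intersection(g_condition.index)
    gt, gc = g_test.loc[common], g_condition.loc[common]
    ok = gt.notna() & gc.notna()
    if ok.sum() >= 2 and gt[ok].std() > 0 and gc[ok].std() > 0:
        r = float(np.corrcoef(gt[ok], gc[ok])[0, 1])
        if abs(r) > 0.999:
            return EqtlResult(feature_id, level, np.nan, np.nan, np.nan,
                              np.nan, int(ok.sum()), status="collinear")
    cov = pd.DataFrame({"condition_dosage": g_condition})
    if covariates is not None:
        cov = pd.DataFrame(covariates).join(cov, how="inner")
    return fit_eqtl(y, g_test, cov, feature_id=feature_id, level=level,
                    log1p=log1p)


def run_multilevel(
    level_matrices: Mapping[str, pd.DataFrame],
    g,
    covariates: Optional[pd.DataFrame] = None,
    *,
    condition_on=None,
    log1p: bool = False,
) -> list[EqtlResult]:
    """One eQTL fit per feature per quantification level.

    ``level_matrices`` maps a level tag to a feature x sample DataFrame (or
    NormalizedMatrix).  Sample ids must match the genotype index exactly.
    Results come back in stable (level, feature_id) order."""
    g = pd.Series(g, dtype=float)
    results: list[EqtlResult] = []
    for lvl in sorted(level_matrices):
        mat = level_matrices[lvl]
        if isinstance(mat, pd.DataFrame):
            values = mat
        elif hasattr(mat, "values") and isinstance(mat.values, pd.DataFrame):
            values = mat.values  # NormalizedMatrix
        elif hasattr(mat, "counts"):
            values = mat.counts  # CountMatrix
        else:
            raise TypeError(f"unsupported matrix type for level {lvl!r}")
        if set(values.columns) != set(g.index):
            raise ValueError(f"sample ids of level {lvl!r} do not match genotypes")
        for fid in sorted(values.index):
            y = values.loc[fid]
            y.index = values.columns
            if condition_on is not None:
                res = conditional_eqtl(y, g, condition_on, covariates,
                                       feature_id=fid, level=lvl, log1p=log1p)
            else:
                res = fit_eqtl(y, g, covariates, feature_id=fid, level=lvl,
                               log1p=log1p)
            results.append(res)
    return results


#: Expected direction of effect of the inclusion-promoting minor allele on
#: the packaged cassette-exon feature set (signs; 0 = no significant effect).
FIG5_EXPECTATION: dict[str, int] = {
    "transcript:dE8": -1,
    "junction:e7-e8": +1,
    "junction:e8-e9": +1,
    "junction:e7-e9": -1,
    "site:e8_acceptor": +1,
    "site:e8_donor": +1,
    "intron:7": -1,
    "intron:8": -1,
    "gene:TYK2like": 0,
}

#: The eight signed features of the expectation (the gene-level zero entry
#: is assessed separately, as lack of significance).
FIG5_SIGNED: dict[str, int] = {
    k: v for k, v in FIG5_EXPECTATION.items() if v != 0
}


def direction_pattern(
    results: Sequence[EqtlResult],
    expected: Mapping[str, int],
    alpha: float = 0.05,
) -> DirectionReport:
    """Compare fitted effect signs against an expected pattern.

    A feature expected +1/-1 matches when sign(beta) agrees; a feature
    expected 0 matches when it is non-significant at ``alpha``.  Every
    expected feature must appear among the results."""
    by_id = {r.feature_id: r for r in results}
    rows = []
    n_match = 0
    for fid, exp_sign in expected.items():
        if fid not in by_id:
            raise KeyError(f"expected feature {fid!r} missing from results")
        r = by_id[fid]
        obs = int(np.sign(r.beta)) if np.isfinite(r.beta) else 0
        if exp_sign == 0:
            match = bool(np.isnan(r.p) or r.p >= alpha)
        else:
            match = obs == exp_sign
        n_match += match
        rows.append({"feature_id": fid, "level": r.level, "expected": exp_sign,
                     "beta": r.beta, "p": r.p, "observed_sign": obs,
                     "match": match})
    table = pd.DataFrame(rows).set_index("feature_id")
    return DirectionReport(table, n_match, len(expected))


def benjamini_hochberg(pvalues: Sequence[float], alpha: float = 0.05):
    """FDR-adjusted p-values (off by default in the pipeline; the primary
    analysis reports raw per-feature p-values)."""
    reject, adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject, adj


def results_to_frame(results: Sequence[EqtlResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "level": r.level,
                "beta": r.beta,
                "se": r.se,
                "t": r.t,
                "p": r.p,
                "n": r.n,
                "status": r.status,
            }
            for r in results
        ]
    )
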