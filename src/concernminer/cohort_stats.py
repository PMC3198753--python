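"""Responder characteristics, response-propensity modelling, and agreement.

Three pieces of the statistical layer around the text pipeline:

* `tabulate_characteristics` — column-percentage tables of covariates for all
  responders versus open-text responders, per panel/survey stratum;
* `fit_propensity` — multivariable logistic regression of the binary
  "provided a meaningful open-ended response" outcome on all covariates
  simultaneously, reported as adjusted odds ratios with Wald 95% CIs
  (maximum likelihood via statsmodels);
* `cohen_kappa` — chance-corrected agreement between an automatic labeling
  and a human review, overall and per category (one-vs-rest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import pct

__all__ = [
    "tabulate_characteristics",
    "fit_propensity",
    "PropensityFit",
    "cohen_kappa",
    "kappa_per_category",
    "landis_koch_label",
]

# Reference levels of the standard covariate set (first level of each).
DEFAULT_REFERENCES = {
    "sex": "Male",
    "birth_year": "Before 1960",
    "education": "High school or less",
    "marital_status": "Married",
    "race_ethnicity": "White non-Hispanic",
    "deployment": "No",
    "rank": "Enlisted",
    "component": "Reserve/Guard",
    "branch": "Air Force",
    "occupation": "Others",
    "general_health": "Very good/excellent",
}


def tabulate_characteristics(
    records: pd.DataFrame,
    covariates: list[str],
    outcome_col: str = "outcome",
    stratum_col: str | None = "stratum",
) -> pd.DataFrame:
    """Column percentages (one decimal, half-up) per covariate level, for all
    records and for open-text responders, within each stratum."""
    strata = (
        sorted(records[stratum_col].unique())
        if stratum_col is not None and stratum_col in records
        else ["all"]
    )
    rows = []
    for s in strata:
        sub = (
            records
            if s == "all" and (stratum_col is None or stratum_col not in records)
            else records[records[stratum_col] == s]
        )
        responders = sub[sub[outcome_col].astype(bool)]
        for cov in covariates:
            level_counts = sub[cov].value_counts()
            resp_counts = responders[cov].value_counts()
            for level in level_counts.index:
                rows.append(
                    {
                        "stratum": s,
                        "covariate": cov,
                        "level": level,
                        "n_all": int(level_counts[level]),
                        "pct_all": pct(level_counts[level], len(sub)),
                        "n_responders": int(resp_counts.get(level, 0)),
                        "pct_responders": (
                            pct(resp_counts.get(level, 0), len(responders))
                            if len(responders)
                            else float("nan")
                        ),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PropensityFit:
    """Adjusted-odds-ratio table plus the underlying statsmodels result."""

    table: pd.DataFrame  # covariate, level, aor, ci_low, ci_high, reference, excludes_1
    n_used: int
    n_dropped_missing: int
    result: object = None

    def aor(self, covariate: str, level: str) -> float:
        row = self.table[
            (self.table["covariate"] == covariate) & (self.table["level"] == level)
        ]
        return float(row["aor"].iloc[0])


def _design(records, covariates, references):
    X = pd.DataFrame(index=records.index)
    names = []  # (covariate, level) per column
    for cov in covariates:
        ref = references.get(cov, sorted(records[cov].unique())[0])
        levels = [l for l in sorted(records[cov].unique()) if l != ref]
        for level in levels:
            X[f"{cov}[{level}]"] = (records[cov] == level).astype(float)
            names.append((cov, level, ref))
    return X, names


def fit_propensity(
    records: pd.DataFrame,
    covariates: list[str],
    outcome_col: str = "outcome",
    references: dict[str, str] | None = None,
    keep_missing: tuple[str, ...] = ("general_health",),
    missing_token: str = "Missing",
) -> PropensityFit:
    """Multivariable logistic fit of response propensity; AOR = exp(beta),
    Wald 95% CI = exp(beta +/- 1.96 SE).

    Complete cases only: rows with missing covariate values are dropped,
    except covariates in `keep_missing`, where an explicit Missing level is
    retained as a category of its own (self-rated health is routinely
    reported this way). Separation or a singular design raises with the
    offending covariate named.
    """
    references = references or DEFAULT_REFERENCES
    work = records.copy()
    for cov in covariates:
        if cov in keep_missing:
            work[cov] = work[cov].fillna(missing_token)
    complete = work.dropna(subset=covariates)
    n_dropped = len(work) - len(complete)

    X, names = _design(complete, covariates, references)
    y = complete[outcome_col].astype(int)
    Xc = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        bad = _singular_columns(Xc)
        raise ValueError(f"singular design matrix; offending column(s): {bad}")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100, tol=1e-8)
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely here
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        bad = [c for c, se in zip(Xc.columns, res.bse) if not np.isfinite(se)]
        raise ValueError(f"separation suspected; unstable column(s): {bad}")

    rows = []
    seen_ref = set()
    for (cov, level, ref), col in zip(names, X.columns):
        if cov not in seen_ref:
            rows.append(
                {
                    "covariate": cov,
                    "level": ref,
                    "aor": 1.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "reference": True,
                    "excludes_1": False,
                }
            )
            seen_ref.add(cov)
        beta = res.params[col]
        se = res.bse[col]
        lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
        rows.append(
            {
                "covariate": cov,
                "level": level,
                "aor": float(np.exp(beta)),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "reference": False,
                "excludes_1": bool(lo > 1.0 or hi < 1.0),
            }
        )
    return PropensityFit(
        table=pd.DataFrame(rows),
        n_used=len(complete),
        n_dropped_missing=n_dropped,
        result=res,
    )


def _singular_columns(X: pd.DataFrame) -> list[str]:
    bad = []
    base_rank = np.linalg.matrix_rank(X.to_numpy())
    for col in X.columns:
        if col == "const":
            continue
        if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == base_rank:
            bad.append(col)
    return bad or list(X.columns)


# --------------------------------------------------------------------------
# agreement
# --------------------------------------------------------------------------

def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), chance agreement from the
    product of the two raters' marginals. Both raters constant and identical
    (p_e = 1) is perfect agreement, kappa = 1."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label sequences differ in length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired labels")
    cats = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    p_e = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    )
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_per_category(labels_a, labels_b) -> dict:
    """One-vs-rest kappa for each category present in either labeling."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    cats = np.union1d(a, b)
    return {
        str(c): cohen_kappa((a == c).astype(int), (b == c).astype(int)) for c in cats
    }


def landis_koch_label(kappa: float) -> str:
    """Conventional qualitative band for a kappa value (annotation only)."""
    bands = [
        (0.0, "poor"),
        (0.20, "slight"),
        (0.40, "fair"),
        (0.60, "moderate"),
        (0.80, "substantial"),
        (1.0 + 1e-12, "almost perfect"),
    ]
    for upper, name in bands:
        if kappa <= upper:
            return name
    return "almost perfect"
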