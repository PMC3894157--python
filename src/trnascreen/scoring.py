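"""Wild-type-referenced sigma scoring and phenotype classification.

Each strain's mean relative growth parameter is projected onto the
empirical distribution of the wild-type replicates for the same condition:
sigma = (x - mu_WT) / sd_WT, the number of wild-type standard deviations
from the wild-type mean. |sigma| > 2 is a non-normal phenotype, |sigma| > 3
a strong one, giving five classes from highly_impaired to highly_improved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import WT

__all__ = [
    "WTReference",
    "PhenotypeClass",
    "CLASSES",
    "build_wt_reference",
    "sigma_score",
    "classify_phenotype",
    "score_library",
    "assemble_condition_matrix",
    "summarize_condition",
    "rate_yield_correlation",
]

#: phenotype classes in sigma order
CLASSES = ("highly_impaired", "impaired", "normal", "improved", "highly_improved")

PhenotypeClass = str


@dataclass(frozen=True)
class WTReference:
    """Empirical wild-type distribution for one condition and parameter."""

    condition: str
    parameter: str
    mu_wt: float
    sd_wt: float
    n_wt: int


def build_wt_reference(
    values, condition: str = "", parameter: str = "yield"
) -> WTReference:
    """Pool wild-type relative values (across plates of one condition)
    into a reference: sample mean and sd (n-1 denominator).

    Requires at least 3 values and non-zero spread.
    """
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 3:
        raise ValueError(f"need >= 3 wild-type values, got {len(vals)}")
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate reference: wild-type values have zero spread")
    return WTReference(
        condition=condition,
        parameter=parameter,
        mu_wt=float(np.mean(vals)),
        sd_wt=sd,
        n_wt=len(vals),
    )


def sigma_score(x: float, ref: WTReference) -> float:
    """sigma = (x - mu_WT) / sd_WT."""
    if not np.isfinite(x):
        raise ValueError("sigma_score requires a finite relative value")
    return (x - ref.mu_wt) / ref.sd_wt


def classify_phenotype(sigma: float) -> PhenotypeClass:
    """Five-class call from sigma; boundary ties go to the more extreme
    class (sigma = -2 is impaired, sigma = 3 is highly_improved)."""
    if not np.isfinite(sigma):
        raise ValueError("classify_phenotype requires a finite sigma")
    if sigma <= -3:
        return "highly_impaired"
    if sigma <= -2:
        return "impaired"
    if sigma < 2:
        return "normal"
    if sigma < 3:
        return "improved"
    return "highly_improved"


def score_library(
    rel_params: pd.DataFrame,
    strain_annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """RelativeParams table → long sigma-score table.

    For each condition the wild-type reference is built by pooling WT
    rows (one per plate × bio_rep) of that condition. Each deletion
    strain's sigma is computed on the mean of its biological-replicate
    means. A strain observed only as lethal gets status ``lethal``; one
    never observed, ``missing``; both carry no sigma.

    Output columns: strain, condition, parameter, sigma, status, class,
    sem (SEM over biological replicates of the relative value).
    """
    required = {"strain", "condition", "bio_rep", "rel_rate", "rel_yield", "lethal"}
    missing_cols = required - set(rel_params.columns)
    if missing_cols:
        raise ValueError(f"relative-params table missing columns {sorted(missing_cols)}")
    if "missing" not in rel_params.columns:
        rel_params = rel_params.assign(missing=False)

    rows = []
    for condition, cond_df in rel_params.groupby("condition", sort=True):
        wt = cond_df[cond_df["strain"] == WT]
        refs = {
            "rate": build_wt_reference(wt["rel_rate"], condition, "rate"),
            "yield": build_wt_reference(wt["rel_yield"], condition, "yield"),
        }
        strains = cond_df[cond_df["strain"] != WT]
        for strain, sdf in strains.groupby("strain", sort=True):
            for parameter, col in (("rate", "rel_rate"), ("yield", "rel_yield")):
                scored = sdf[~sdf["lethal"] & ~sdf["missing"]]
                if len(scored) == 0:
                    status = "lethal" if sdf["lethal"].any() else "missing"
                    rows.append(
                        (strain, condition, parameter, np.nan, status, None, np.nan)
                    )
                    continue
                # mean of technical-rep means per bio rep, then across bio reps
                per_bio = scored.groupby("bio_rep")[col].mean()
                x = float(per_bio.mean())
                sem = (
                    float(per_bio.std(ddof=1) / np.sqrt(len(per_bio)))
                    if len(per_bio) > 1
                    else np.nan
                )
                sig = sigma_score(x, refs[parameter])
                rows.append(
                    (strain, condition, parameter, sig, "scored",
                     classify_phenotype(sig), sem)
                )
    return pd.DataFrame(
        rows,
        columns=["strain", "condition", "parameter", "sigma", "status", "class", "sem"],
    )


def assemble_condition_matrix(
    scores: pd.DataFrame,
    strain_annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long score table → strains × (condition, parameter) matrix table.

    Rows ordered by amino acid, then family, then strain when an
    annotation table (columns strain, aa, family) is given, else
    alphabetically. Every (strain, condition, parameter) must be unique.
    Cell content is the sigma value for scored cells and the status
    string otherwise (lethal/missing preserved).
    """
    dup = scores.duplicated(subset=["strain", "condition", "parameter"])
    if dup.any():
        d = scores[dup].iloc[0]
        raise ValueError(
            "conflicting duplicate scores for "
            f"({d['strain']}, {d['condition']}, {d['parameter']})"
        )
    table = scores.copy()
    if strain_annotation is not None:
        table = table.merge(strain_annotation, on="strain", how="left")
        order_cols = ["aa", "family", "strain"]
    else:
        table["aa"] = ""
        table["family"] = ""
        order_cols = ["strain"]
    strain_order = (
        table[["strain", "aa", "family"]]
        .drop_duplicates()
        .sort_values(order_cols)["strain"]
        .tolist()
    )
    wide = table.pivot(
        index="strain", columns=["condition", "parameter"], values="sigma"
    )
    status = table.pivot(
        index="strain", columns=["condition", "parameter"], values="status"
    )
    # cells that were never scored keep their status; absent combinations
    # are missing
    status = status.fillna("missing")
    wide = wide.reindex(strain_order)
    status = status.reindex(strain_order)
    wide.attrs["status"] = status
    return wide


def summarize_condition(
    scores: pd.DataFrame, condition: str, parameter: str
) -> dict[str, float]:
    """Percent of scored strains in pooled phenotype groups.

    impaired pools sigma <= -2 classes, improved pools sigma >= 2;
    denominators are scored strains only (lethal and missing excluded,
    counts reported alongside).
    """
    sel = scores[
        (scores["condition"] == condition) & (scores["parameter"] == parameter)
    ]
    scored = sel[sel["status"] == "scored"]
    n = len(scored)
    if n == 0:
        raise ValueError(
            f"no scored strains for condition={condition!r} parameter={parameter!r}"
        )
    n_impaired = int((scored["sigma"] <= -2).sum())
    n_improved = int((scored["sigma"] >= 2).sum())
    n_lethal = int((sel["status"] == "lethal").sum())
    n_missing = int((sel["status"] == "missing").sum())
    return {
        "pct_impaired": 100.0 * n_impaired / n,
        "pct_improved": 100.0 * n_improved / n,
        "pct_normal": 100.0 * (n - n_impaired - n_improved) / n,
        "n_scored": n,
        "n_lethal": n_lethal,
        "n_missing": n_missing,
    }


def rate_yield_correlation(
    scores: pd.DataFrame, condition: str
) -> tuple[float, float, int]:
    """Pearson correlation between sigma_rate and sigma_yield over strains
    scored for both parameters in a condition; two-sided p-value."""
    sel = scores[(scores["condition"] == condition) & (scores["status"] == "scored")]
    wide = sel.pivot(index="strain", columns="parameter", values="sigma").dropna()
    if len(wide) < 3 or "rate" not in wide or "yield" not in wide:
        raise ValueError("need >= 3 strains scored for both parameters")
    r, p = stats.pearsonr(wide["rate"], wide["yield"])
    return float(r), float(p), len(wide)


def matrix_to_tsv(scores: pd.DataFrame, path) -> None:
    """Serialize the long score table (round-trips via read_csv)."""
    scores.to_csv(path, sep="\t", index=False, na_rep="NA")


def matrix_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    df["class"] = df["class"].where(df["class"].notna(), None)
    return df
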