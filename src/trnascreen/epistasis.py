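"""Genetic-interaction scores for co-deleted gene pairs.

Under the multiplicative null the relative fitness of a double deletion is
the product of the singles' fitness; epistasis is the deviation

    epsilon = W_AB - W_A * W_B

with negative values aggravating (the double is worse than expected) and
positive values alleviating. epsilon is computed per biological replicate
and reported as mean +/- SEM over replicates, separately for the growth
rate and growth yield parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EpistasisResult", "epistasis_value", "epistasis_with_error", "score_pairs"]


@dataclass(frozen=True)
class EpistasisResult:
    gene_a: str
    gene_b: str
    parameter: str
    w_a: float
    w_b: float
    w_ab: float
    epsilon: float
    sem: float
    n_reps: int


def epistasis_value(w_a: float, w_b: float, w_ab: float) -> float:
    """epsilon = w_ab - w_a * w_b (multiplicative null)."""
    for name, w in (("w_a", w_a), ("w_b", w_b), ("w_ab", w_ab)):
        if not np.isfinite(w) or w < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {w}")
    return w_ab - w_a * w_b


def epistasis_with_error(
    replicates: pd.DataFrame,
    gene_a: str = "",
    gene_b: str = "",
    parameter: str = "yield",
) -> EpistasisResult:
    """Replicate-paired epistasis with SEM.

    ``replicates`` needs columns ``bio_rep, w_a, w_b, w_ab`` with one
    complete triple per biological replicate; epsilon is computed within
    each replicate, then averaged (SEM = sd/sqrt(n)). At least two
    complete triples are required — SEM is undefined for one.
    """
    required = {"bio_rep", "w_a", "w_b", "w_ab"}
    if missing := required - set(replicates.columns):
        raise ValueError(f"replicate table missing columns {sorted(missing)}")
    complete = replicates.dropna(subset=["w_a", "w_b", "w_ab"])
    dropped = set(replicates["bio_rep"]) - set(complete["bio_rep"])
    if dropped:
        raise ValueError(
            f"incomplete replicate triples for bio_rep labels {sorted(dropped)}"
        )
    if len(complete) < 2:
        raise ValueError("need >= 2 complete replicate triples (SEM undefined)")
    eps = np.array(
        [
            epistasis_value(row.w_a, row.w_b, row.w_ab)
            for row in complete.itertuples()
        ]
    )
    n = len(eps)
    return EpistasisResult(
        gene_a=gene_a,
        gene_b=gene_b,
        parameter=parameter,
        w_a=float(complete["w_a"].mean()),
        w_b=float(complete["w_b"].mean()),
        w_ab=float(complete["w_ab"].mean()),
        epsilon=float(eps.mean()),
        sem=float(eps.std(ddof=1) / np.sqrt(n)),
        n_reps=n,
    )


def score_pairs(rel_params: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Score every (gene_a, gene_b, double_strain) pair for rate and yield.

    ``rel_params`` is the relative-parameter table (strain, condition,
    bio_rep, rel_rate, rel_yield); single and double strains are looked up
    by name. Replicates are paired by bio_rep label; when counts differ
    the intersection of labels is used. Output: one row per pair and
    parameter with epsilon, SEM and n_reps.
    """
    for col in ("gene_a", "gene_b", "double_strain"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table missing column {col!r}")
    # mean over technical replicates (plates) within each bio rep
    per_bio = (
        rel_params.groupby(["strain", "bio_rep"], as_index=False)[
            ["rel_rate", "rel_yield"]
        ].mean()
    )
    out = []
    for pair in pairs.itertuples():
        for parameter, col in (("rate", "rel_rate"), ("yield", "rel_yield")):
            tabs = {}
            for role, strain in (
                ("w_a", pair.gene_a),
                ("w_b", pair.gene_b),
                ("w_ab", pair.double_strain),
            ):
                sub = per_bio[per_bio["strain"] == strain][["bio_rep", col]]
                if sub.empty:
                    raise KeyError(f"strain {strain!r} absent from parameter table")
                tabs[role] = sub.rename(columns={col: role})
            merged = tabs["w_a"].merge(tabs["w_b"], on="bio_rep").merge(
                tabs["w_ab"], on="bio_rep"
            )
            res = epistasis_with_error(merged, pair.gene_a, pair.gene_b, parameter)
            out.append(res)
    return pd.DataFrame(
        [
            (r.gene_a, r.gene_b, r.parameter, r.w_a, r.w_b, r.w_ab, r.epsilon,
             r.sem, r.n_reps)
            for r in out
        ],
        columns=[
            "gene_a", "gene_b", "parameter", "w_a", "w_b", "w_ab", "epsilon",
            "sem", "n_reps",
        ],
    )
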