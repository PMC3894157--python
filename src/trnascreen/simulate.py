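"""Synthetic plate-reader data with known planted structure.

Emulates a robotic growth screen of a deletion library: 96-well plates of
OD600 time series sampled every 30 minutes, each plate carrying wild-type
reference wells and blanks, with three biological replicates and many
technical replicates per strain. Strain effects are planted as multipliers
on the wild-type growth rate and carrying capacity, double deletions are
constructed against a multiplicative fitness null with a planted deviation
(epistasis), and upstream flanking sequences carry consensus elements at
anchored positions. Everything downstream of the wet lab is therefore
testable against ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "LibraryTruth",
    "TruthSpec",
    "logistic_od",
    "simulate_plate",
    "simulate_library",
    "simulate_flanks",
]

#: reserved strain names on plate maps
WT = "WT"
BLANK = "BLANK"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated screen.

    Defaults mirror a standard yeast OD600 plate run: readings every 0.5 h
    ("every 30 minutes"), 3 biological and 36 technical replicates per
    strain, 96-well plates with at least 4 wild-type wells each.
    """

    n_strains: int = 24
    conditions: tuple[str, ...] = ("YPD",)
    n_bio_reps: int = 3
    n_tech_reps: int = 36
    wells_per_plate: int = 96
    n_wt_wells: int = 4
    n_blank_wells: int = 2
    t_max: float = 36.0
    dt: float = 0.5
    od0: float = 0.02
    blank_od: float = 0.08
    K_wt: float = 1.2
    r_wt: float = 0.40
    lag_wt: float = 2.0
    noise_sd: float = 0.005
    cv_bio: float = 0.03
    cv_well: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "dt": self.dt,
            "t_max": self.t_max,
            "od0": self.od0,
            "K_wt": self.K_wt,
            "r_wt": self.r_wt,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.n_tech_reps < 1:
            raise ValueError("n_tech_reps must be >= 1")
        if self.n_wt_wells < 1:
            raise ValueError("every plate needs at least one wild-type well")
        if self.noise_sd < 0 or self.cv_bio < 0 or self.cv_well < 0:
            raise ValueError("noise_sd, cv_bio and cv_well must be non-negative")
        if self.lag_wt < 0:
            raise ValueError("lag_wt must be non-negative")
        if self.n_points * self.dt < self.lag_wt:
            raise ValueError("no growth phase sampled: t_max shorter than lag")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.t_max + 0.5 * self.dt, self.dt)

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass
class LibraryTruth:
    """Planted ground truth for one simulated library.

    ``effects`` has one row per strain: multipliers on the wild-type rate
    and carrying capacity plus a lethality flag. ``pairs`` records double
    deletions with the planted epistasis of each parameter (the double's
    multipliers are constructed as w_a*w_b + eps, so eps=0 reproduces the
    multiplicative null exactly). ``elements`` lists planted upstream
    elements per gene.
    """

    effects: pd.DataFrame
    pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_a", "gene_b", "double_strain", "eps_yield", "eps_rate"]
        )
    )
    elements: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "element_id", "anchor"])
    )

    def effect(self, strain: str) -> tuple[float, float, bool]:
        row = self.effects.loc[self.effects["strain"] == strain]
        if row.empty:
            raise KeyError(f"unknown strain {strain!r}")
        r = row.iloc[0]
        return float(r["effect_rate"]), float(r["effect_yield"]), bool(r["lethal"])

    @classmethod
    def all_wildtype(cls, strains: list[str]) -> "LibraryTruth":
        return cls(
            effects=pd.DataFrame(
                {
                    "strain": strains,
                    "effect_rate": 1.0,
                    "effect_yield": 1.0,
                    "lethal": False,
                }
            )
        )


@dataclass(frozen=True)
class TruthSpec:
    """Distribution of planted effects across the library.

    Fractions of strains assigned (deterministically, by index) to each
    effect group; remaining strains are null (multiplier 1.0).
    """

    frac_yield_effect: float = 0.10
    frac_rate_effect: float = 0.10
    frac_lethal: float = 0.02
    yield_multiplier: float = 0.8
    rate_multiplier: float = 0.8

    def __post_init__(self) -> None:
        for name in ("frac_yield_effect", "frac_rate_effect", "frac_lethal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_yield_effect + self.frac_rate_effect + self.frac_lethal > 1.0:
            raise ValueError("effect fractions sum to more than 1")


def _stream(seed: int, *keys) -> np.random.Generator:
    """Child RNG derived by stable hashing of string/int keys.

    crc32 keeps every derived entropy word below 2**32, so small master
    seeds stay small and runs are reproducible across platforms.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        words.append(zlib.crc32(str(k).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


def logistic_od(
    t: np.ndarray,
    K: float,
    r: float,
    od0: float,
    lag: float,
    blank: float = 0.0,
) -> np.ndarray:
    """Closed-form lagged logistic growth curve (no noise).

    OD(t) = blank + od0 for t < lag, then
    OD(t) = blank + K / (1 + ((K - od0)/od0) * exp(-r (t - lag))).
    Continuous at t = lag. A flat K = od0 curve represents no growth.
    """
    t = np.asarray(t, dtype=float)
    od = np.full_like(t, od0, dtype=float)
    grown = t >= lag
    if K > 0 and od0 > 0:
        od[grown] = K / (1.0 + ((K - od0) / od0) * np.exp(-r * (t[grown] - lag)))
    return blank + od


def default_assignments(config: SimConfig, strains: list[str]) -> dict[str, str]:
    """Row-major well→strain map filling one plate: WT wells first, then
    blanks, then the given strains; leftover wells stay blank."""
    wells = _well_names(config.wells_per_plate)
    assignment: dict[str, str] = {}
    idx = 0
    for _ in range(config.n_wt_wells):
        assignment[wells[idx]] = WT
        idx += 1
    for _ in range(config.n_blank_wells):
        assignment[wells[idx]] = BLANK
        idx += 1
    for s in strains:
        if idx >= len(wells):
            raise ValueError("more strains than wells on the plate")
        assignment[wells[idx]] = s
        idx += 1
    return assignment


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    n_cols = 12 if n <= 96 else 24
    names = []
    for r in range(int(np.ceil(n / n_cols))):
        for c in range(n_cols):
            names.append(f"{rows[r]}{c + 1:02d}")
    return names[:n]


def simulate_plate(
    config: SimConfig,
    assignments: dict[str, str],
    truth: LibraryTruth | None = None,
    seed: int = 0,
    bio_rep: int = 1,
    bio_multipliers: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one plate read-out.

    Returns ``(reads, plate_map)``: a long-format table ``time_h, well, od``
    and a map ``well, strain, bio_rep``. Strain-specific carrying capacity
    and rate come from the truth table's multipliers; lethal strains stay
    flat at the inoculum. Additive Gaussian noise (sd ``noise_sd``) is
    truncated at zero. Deterministic given ``seed``.

    ``bio_multipliers`` optionally injects per-(strain, bio_rep) lognormal
    variation shared across technical replicates on different plates.
    """
    if truth is None:
        truth = LibraryTruth.all_wildtype(
            sorted({s for s in assignments.values() if s not in (WT, BLANK)})
        )
    known = set(truth.effects["strain"]) | {WT, BLANK}
    for well, strain in assignments.items():
        if strain not in known:
            raise ValueError(f"unknown strain {strain!r} in well {well}")

    rng = _stream(seed, "plate")
    times = config.times
    rows_t, rows_w, rows_od = [], [], []
    map_rows = []
    for well in sorted(assignments):
        strain = assignments[well]
        if strain == BLANK:
            clean = np.full_like(times, config.blank_od)
        else:
            if strain == WT:
                m_rate, m_yield, lethal = 1.0, 1.0, False
            else:
                m_rate, m_yield, lethal = truth.effect(strain)
            if bio_multipliers is not None and strain in bio_multipliers:
                b_r, b_y = bio_multipliers[strain]
                m_rate, m_yield = m_rate * b_r, m_yield * b_y
            if lethal:
                K, r = config.od0, 0.0
            else:
                # well-to-well culture variability (inoculum, micro-
                # environment): independent lognormal per well, mean 1
                if config.cv_well > 0:
                    s = np.sqrt(np.log1p(config.cv_well**2))
                    m_rate = m_rate * float(np.exp(rng.normal(-0.5 * s**2, s)))
                    m_yield = m_yield * float(np.exp(rng.normal(-0.5 * s**2, s)))
                K = max(config.K_wt * m_yield, config.od0)
                r = config.r_wt * m_rate
            clean = logistic_od(
                times, K, r, config.od0, config.lag_wt, config.blank_od
            )
        noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)
        noisy = np.maximum(noisy, 0.0)
        rows_t.append(times)
        rows_w.append(np.repeat(well, len(times)))
        rows_od.append(noisy)
        map_rows.append((well, strain, bio_rep))

    reads = pd.DataFrame(
        {
            "time_h": np.concatenate(rows_t),
            "well": np.concatenate(rows_w),
            "od": np.concatenate(rows_od),
        }
    )
    plate_map = pd.DataFrame(map_rows, columns=["well", "strain", "bio_rep"])
    return reads, plate_map


def make_library_truth(
    strains: list[str], truth_spec: TruthSpec, seed: int = 0
) -> LibraryTruth:
    """Assign planted effects deterministically: the first
    ``frac_lethal`` of strains lethal, the next ``frac_yield_effect`` with
    a yield multiplier, the next ``frac_rate_effect`` with a rate
    multiplier, the rest null."""
    n = len(strains)
    n_lethal = int(round(truth_spec.frac_lethal * n))
    n_yield = int(round(truth_spec.frac_yield_effect * n))
    n_rate = int(round(truth_spec.frac_rate_effect * n))
    eff_rate = np.ones(n)
    eff_yield = np.ones(n)
    lethal = np.zeros(n, dtype=bool)
    lethal[:n_lethal] = True
    sl_y = slice(n_lethal, n_lethal + n_yield)
    sl_r = slice(n_lethal + n_yield, n_lethal + n_yield + n_rate)
    eff_yield[sl_y] = truth_spec.yield_multiplier
    eff_rate[sl_r] = truth_spec.rate_multiplier
    return LibraryTruth(
        effects=pd.DataFrame(
            {
                "strain": strains,
                "effect_rate": eff_rate,
                "effect_yield": eff_yield,
                "lethal": lethal,
            }
        )
    )


def add_double_deletions(
    truth: LibraryTruth,
    pairs: list[tuple[str, str, float, float]],
) -> LibraryTruth:
    """Construct double-deletion strains with planted epistasis.

    Each entry is ``(gene_a, gene_b, eps_yield, eps_rate)``. The double
    strain's multipliers are w_a*w_b + eps per parameter (clipped at 0),
    so the multiplicative null holds exactly when eps = 0.
    """
    eff = truth.effects.set_index("strain")
    new_rows = []
    pair_rows = []
    for gene_a, gene_b, eps_yield, eps_rate in pairs:
        for g in (gene_a, gene_b):
            if g not in eff.index:
                raise KeyError(f"unknown single-deletion strain {g!r}")
        w_ab_yield = max(
            eff.loc[gene_a, "effect_yield"] * eff.loc[gene_b, "effect_yield"]
            + eps_yield,
            0.0,
        )
        w_ab_rate = max(
            eff.loc[gene_a, "effect_rate"] * eff.loc[gene_b, "effect_rate"]
            + eps_rate,
            0.0,
        )
        name = f"{gene_a}|{gene_b}"
        new_rows.append((name, w_ab_rate, w_ab_yield, False))
        pair_rows.append((gene_a, gene_b, name, eps_yield, eps_rate))
    effects = pd.concat(
        [
            truth.effects,
            pd.DataFrame(
                new_rows, columns=["strain", "effect_rate", "effect_yield", "lethal"]
            ),
        ],
        ignore_index=True,
    )
    pair_df = pd.DataFrame(
        pair_rows,
        columns=["gene_a", "gene_b", "double_strain", "eps_yield", "eps_rate"],
    )
    if len(truth.pairs):
        pair_df = pd.concat([truth.pairs, pair_df], ignore_index=True)
    return LibraryTruth(effects=effects, pairs=pair_df, elements=truth.elements)


def simulate_library(
    config: SimConfig,
    truth_spec: TruthSpec | LibraryTruth | None = None,
    seed: int | None = None,
) -> tuple[LibraryTruth, dict[str, list[tuple[pd.DataFrame, pd.DataFrame]]]]:
    """Simulate the whole screen: all plates for all conditions.

    Returns the planted truth and, per condition, a list of
    ``(reads, plate_map)`` plates. Technical replicates of a strain are
    distributed across plates; each plate carries its own wild-type wells.
    Biological-replicate variation is a lognormal multiplier (CV
    ``cv_bio``) on rate and capacity, shared by all technical replicates
    of a (strain, bio_rep) and drawn once per condition.
    """
    if seed is None:
        seed = config.seed
    strains = [f"strain{i:04d}" for i in range(config.n_strains)]
    if truth_spec is None:
        truth_spec = TruthSpec()
    if isinstance(truth_spec, LibraryTruth):
        truth = truth_spec
        strains = list(truth.effects["strain"])
    else:
        truth = make_library_truth(strains, truth_spec, seed)
        strains = list(truth.effects["strain"])

    capacity = config.wells_per_plate - config.n_wt_wells - config.n_blank_wells
    per_bio = max(config.n_tech_reps // config.n_bio_reps, 1)
    plates_by_condition: dict[str, list[tuple[pd.DataFrame, pd.DataFrame]]] = {}
    for condition in config.conditions:
        plates = []
        plate_idx = 0
        for bio_rep in range(1, config.n_bio_reps + 1):
            bio_rng = _stream(seed, condition, "bio", bio_rep)
            sigma = np.sqrt(np.log1p(config.cv_bio**2))
            bio_mult = {
                s: (
                    float(np.exp(bio_rng.normal(-0.5 * sigma**2, sigma))),
                    float(np.exp(bio_rng.normal(-0.5 * sigma**2, sigma))),
                )
                for s in strains
            }
            # tech replicates of every strain for this bio rep, packed into plates
            slots = [s for s in strains for _ in range(per_bio)]
            for start in range(0, len(slots), capacity):
                chunk = slots[start : start + capacity]
                assignments = default_assignments(config, chunk)
                plate_seed = int(
                    _stream(seed, condition, "plate", plate_idx).integers(2**31)
                )
                plates.append(
                    simulate_plate(
                        config,
                        assignments,
                        truth,
                        seed=plate_seed,
                        bio_rep=bio_rep,
                        bio_multipliers=bio_mult,
                    )
                )
                plate_idx += 1
        plates_by_condition[condition] = plates
    return truth, plates_by_condition


# ---------------------------------------------------------------------------
# upstream flanking sequences


def simulate_flanks(
    genes: list[str],
    element_plan: dict[str, list[tuple[str, str, int]]] | None = None,
    bg_model: dict[str, float] | None = None,
    flank_len: int = 200,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate upstream flanks with planted elements.

    ``element_plan`` maps gene → list of ``(element_id, consensus, anchor)``
    with the anchor an upstream position (negative; position −1 is the base
    adjacent to the mature-tRNA start at 0). The consensus (IUPAC) is
    instantiated at the anchor; the remainder is i.i.d. from ``bg_model``
    (default uniform ACGT). Returns ``(records, truth)`` where records are
    ``(header, sequence)`` pairs ready for FASTA writing.
    """
    if flank_len < 60:
        raise ValueError("flank_len must be >= 60")
    if bg_model is None:
        bg_model = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    bases = sorted(bg_model)
    probs = np.array([bg_model[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    element_plan = element_plan or {}

    iupac = _IUPAC_SETS
    records = []
    truth_rows = []
    for gene in genes:
        rng = _stream(seed, "flank", gene)
        seq = rng.choice(list(bases), size=flank_len, p=probs)
        for element_id, consensus, anchor in element_plan.get(gene, []):
            if not -flank_len <= anchor <= -1:
                raise ValueError(
                    f"anchor {anchor} outside flank [-{flank_len}, -1] for {gene}"
                )
            offset = flank_len + anchor
            if offset + len(consensus) > flank_len:
                raise ValueError(
                    f"element {element_id} at {anchor} overruns the tRNA start"
                )
            for i, sym in enumerate(consensus.upper()):
                choices = sorted(iupac[sym])
                seq[offset + i] = choices[int(rng.integers(len(choices)))]
            truth_rows.append((gene, element_id, anchor))
        header = f"{gene} upstream=-{flank_len}..-1"
        records.append((header, "".join(seq)))
    truth = pd.DataFrame(truth_rows, columns=["gene", "element_id", "anchor"])
    return records, truth


_IUPAC_SETS: dict[str, set[str]] = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "U": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (header, sequence) pairs as FASTA, 70 columns."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_tsv(truth: LibraryTruth, path) -> None:
    truth.effects.to_csv(path, sep="\t", index=False)
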