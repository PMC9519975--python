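"""Synthetic study populations with known ground truth.

Emulates the structure of a long-term primate field study: a handful of
social groups observed for a decade, overlapping generations, long alpha-male
tenures with high reproductive skew (the alpha sires a fixed share of infants
unless the dam descends from him — inbreeding avoidance), male dispersal with
occasional sibling co-migration, and monthly scan-sampled sociality records.

Observations are generated from the latent Gaussian decomposition the models
assume: eta = x'beta + sum of ten random components + residual, with the
binomial response Binom(n_scans, logistic(eta)) and the Poisson response
Poisson(n_scans * exp(eta)).  Breeding values follow the pedigree (founders
N(0, sigma_A^2); offspring mid-parent plus Mendelian sampling deflated by
parental inbreeding), so the realized covariance of the animal term is
sigma_A^2 * A exactly.

Everything is deterministic under a seed, and generated datasets pass the
phenotype filters at their default thresholds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping

import numpy as np
import pandas as pd

from .pedigree import (
    AlphaTenure,
    Pedigree,
    PedigreeRecord,
    additive_relationship_matrix,
    prune_pedigree,
    validate_pedigree,
)
from .phenotypes import (
    Design,
    DesignSpec,
    MonthlyRecord,
    build_design,
    filter_records,
    records_to_frame,
)

__all__ = [
    "TrueParameters",
    "Population",
    "SyntheticDataset",
    "simulate_population",
    "simulate_breeding_values",
    "simulate_observations",
    "make_dataset",
]

#: latent variance components emulating the study's binomial trait
#: (proportions of a unit total phenotypic variance)
DEFAULT_VARIANCES = {
    "ID": 0.050,
    "ID:Year": 0.091,
    "M": 0.005,
    "M:GroupAlpha:Year": 0.045,
    "animal": 0.152,
    "Year": 0.110,
    "Month:Year": 0.208,
    "GroupAlpha": 0.108,
    "GroupAlpha:Year": 0.061,
    "residual": 0.170,
}

#: fixed effects: sociality declines with age, juvenile males exceed females
#: (the sex gap closing with age), larger groups are more social, both ENSO
#: extremes depress sociality, seasonality is weak
DEFAULT_BETA = {
    "intercept": 0.156,
    "age_z": -0.15,
    "age_z2": 0.02,
    "age_z3": 0.01,
    "sex_M": 0.10,
    "age_z:sex_M": -0.08,
    "age_z2:sex_M": 0.02,
    "age_z3:sex_M": 0.0,
    "group_size_z": 0.15,
    "season_sin": 0.01,
    "season_cos": 0.01,
    "enso_cool": -0.12,
    "enso_warm": -0.12,
}


@dataclass
class TrueParameters:
    """Generative ground truth: variances, fixed effects, demography."""

    variances: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCES))
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    mean_scans: float = 32.0
    min_scans: int = 5
    # demography (defaults sized for minutes-scale model fits: ~120 subjects)
    n_groups: int = 4
    n_years: int = 10
    founder_females: int = 8
    founder_males: int = 6
    birth_rate: float = 0.45
    capacity: float = 18.0  # density regulation; equilibrium group size ~25
    paternity_skew: float = 0.73
    female_maturity: int = 6
    sire_min_age: int = 7
    alpha_min_age: int = 10
    dispersal_age: int = 8
    comigration_prob: float = 0.5
    infant_death: float = 0.08
    adult_death: float = 0.03
    old_death: float = 0.15
    old_age: int = 20
    tenure_mean_years: float = 7.0  # long alpha tenures drive paternal sibships
    tenure_max_years: int = 14
    obs_prob: float = 0.47  # sampled subject-months -> ~40 records/subject
    mei_phi: float = 0.8
    mei_sd: float = 0.435
    burnin_years: int = 25
    first_year: int = 2001

    def __post_init__(self):
        if any(v < 0 for v in self.variances.values()):
            raise ValueError("variances must be >= 0")
        if not 0.0 <= self.paternity_skew <= 1.0:
            raise ValueError("paternity skew must be in [0, 1]")

    @property
    def h2_latent(self) -> float:
        return self.variances["animal"] / sum(self.variances.values())

    def with_h2(self, h2: float) -> "TrueParameters":
        """Set the additive share, rescaling the other nine components
        proportionally so V_P and the relative environmental structure are
        unchanged."""
        if not 0.0 <= h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        v = dict(self.variances)
        vp = sum(v.values())
        rest = vp - v["animal"]
        scale = (1.0 - h2) * vp / rest
        out = {k: val * scale for k, val in v.items() if k != "animal"}
        out["animal"] = h2 * vp
        return dc_replace(self, variances=out)


@dataclass
class Population:
    pedigree: Pedigree
    tenures: list
    membership: dict  # (id, year) -> group
    birthdate: dict  # id -> (year, month)
    sex: dict  # id -> "F" | "M"


@dataclass
class SyntheticDataset:
    """Pedigree + tenures + filtered monthly records + realized truth."""

    population: Population
    records: list
    truth: TrueParameters
    realized: dict  # term -> {level: value}, plus "residual" per record
    design: Design

    @property
    def pedigree(self) -> Pedigree:
        return self.population.pedigree

    @property
    def subjects(self) -> list[str]:
        return sorted({r.subject for r in self.records})

    def pruned_amatrix(self):
        pruned = prune_pedigree(self.pedigree, set(self.subjects))
        return additive_relationship_matrix(pruned)

    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------

def _is_descendant_within(parents: Mapping, iid, ancestor, depth) -> bool:
    frontier = [(iid, 0)]
    while frontier:
        cur, d = frontier.pop()
        if d >= depth:
            continue
        for p in parents.get(cur, (None, None)):
            if p is None:
                continue
            if p == ancestor:
                return True
            frontier.append((p, d + 1))
    return False


def simulate_population(params: TrueParameters, seed: int = 0) -> Population:
    """Simulate overlapping-generation demography with skewed paternity.

    Yearly steps: alpha succession (tenure lengths geometric, capped),
    births (sire = current alpha with probability ``paternity_skew`` unless
    the dam is the alpha's daughter or granddaughter, in which case a
    non-alpha resident male is drawn), mortality, and male dispersal at
    maturity with optional sibling co-migration.  Returns the full pedigree,
    the alpha-tenure list covering every observed group-year, and yearly
    group membership.
    """
    if params.n_groups < 1 or params.n_years < 1:
        raise ValueError("need at least one group and one year")
    rng = np.random.default_rng(seed)
    groups = [f"G{g}" for g in range(params.n_groups)]
    y0 = params.first_year - params.burnin_years
    y_end = params.first_year + params.n_years  # exclusive

    sex: dict[str, str] = {}
    birth: dict[str, tuple[int, int]] = {}
    parents: dict[str, tuple] = {}
    group_of: dict[str, str] = {}
    alive: set[str] = set()
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:05d}"

    for g in groups:
        for _ in range(params.founder_females):
            i = new_id()
            sex[i] = "F"
            birth[i] = (y0 - int(rng.integers(6, 16)), int(rng.integers(1, 13)))
            parents[i] = (None, None)
            group_of[i] = g
            alive.add(i)
        for _ in range(params.founder_males):
            i = new_id()
            sex[i] = "M"
            birth[i] = (y0 - int(rng.integers(8, 19)), int(rng.integers(1, 13)))
            parents[i] = (None, None)
            group_of[i] = g
            alive.add(i)

    alpha_of: dict[str, str] = {}
    tenure_end: dict[str, int] = {}
    alpha_years: list[tuple[str, int, str]] = []  # (group, year, alpha)
    membership: dict[tuple[str, int], str] = {}

    def age_of(i: str, year: int) -> float:
        return year - birth[i][0]

    def resident_males(g: str, min_age: float, year: int) -> list[str]:
        return sorted(
            m
            for m in alive
            if sex[m] == "M" and group_of[m] == g and age_of(m, year) >= min_age
        )

    for year in range(y0, y_end):
        # --- alpha succession ---------------------------------------------
        for g in groups:
            a = alpha_of.get(g)
            if a is None or a not in alive or year > tenure_end[g]:
                cand = resident_males(g, params.alpha_min_age, year)
                if not cand:
                    cand = resident_males(g, params.sire_min_age, year)
                if not cand:
                    cand = resident_males(g, 0, year)
                if not cand:
                    # male-less group: the oldest non-alpha male elsewhere
                    # immigrates and takes over
                    outside = sorted(
                        (m for m in alive
                         if sex[m] == "M" and m not in alpha_of.values()),
                        key=lambda m: -age_of(m, year),
                    )
                    if not outside:
                        raise RuntimeError(
                            f"impossible demography: no eligible alpha in {g} "
                            f"year {year}"
                        )
                    group_of[outside[0]] = g
                    cand = [outside[0]]
                choices = [c for c in cand if c != a] or cand
                alpha_of[g] = choices[int(rng.integers(len(choices)))]
                length = int(
                    min(1 + rng.geometric(1.0 / params.tenure_mean_years),
                        params.tenure_max_years)
                )
                tenure_end[g] = year + length - 1
            alpha_years.append((g, year, alpha_of[g]))

        # --- births (density-regulated) -------------------------------------
        gsize = {g: 0 for g in groups}
        for i in alive:
            gsize[group_of[i]] += 1
        for dam in sorted(alive):
            if sex[dam] != "F" or age_of(dam, year) < params.female_maturity:
                continue
            g = group_of[dam]
            br = params.birth_rate / (1.0 + (gsize[g] / params.capacity) ** 2)
            if rng.random() >= br:
                continue
            a = alpha_of[g]
            males = [m for m in resident_males(g, params.sire_min_age, year) if m != dam]
            sire = None
            if rng.random() < params.paternity_skew:
                if _is_descendant_within(parents, dam, a, 2):
                    non_alpha = [m for m in males if m != a]
                    if non_alpha:
                        sire = non_alpha[int(rng.integers(len(non_alpha)))]
                else:
                    sire = a
            else:
                non_alpha = [m for m in males if m != a]
                if non_alpha:
                    sire = non_alpha[int(rng.integers(len(non_alpha)))]
                elif males:
                    sire = males[int(rng.integers(len(males)))]
            if sire is None:
                continue
            child = new_id()
            sex[child] = "F" if rng.random() < 0.5 else "M"
            birth[child] = (year, int(rng.integers(1, 13)))
            parents[child] = (dam, sire)
            group_of[child] = g
            alive.add(child)

        # --- mortality ------------------------------------------------------
        for i in sorted(alive):
            a_i = age_of(i, year)
            p = (
                params.infant_death
                if a_i < 1
                else params.old_death
                if a_i > params.old_age
                else params.adult_death
            )
            if rng.random() < p:
                alive.discard(i)

        # --- male dispersal with sibling co-migration -----------------------
        movers = [
            m
            for m in sorted(alive)
            if sex[m] == "M"
            and age_of(m, year) == params.dispersal_age
            and alpha_of.get(group_of[m]) != m
        ]
        for m in movers:
            if m not in alive:
                continue
            dest = groups[int(rng.integers(len(groups)))]
            while dest == group_of[m] and len(groups) > 1:
                dest = groups[int(rng.integers(len(groups)))]
            src = group_of[m]
            group_of[m] = dest
            if rng.random() < params.comigration_prob:
                sibs = [
                    s
                    for s in sorted(alive)
                    if s != m
                    and sex[s] == "M"
                    and group_of[s] == src
                    and alpha_of.get(src) != s
                    and abs(age_of(s, year) - params.dispersal_age) <= 2
                    and (
                        (parents[s][0] is not None and parents[s][0] == parents[m][0])
                        or (parents[s][1] is not None and parents[s][1] == parents[m][1])
                    )
                ]
                if sibs:
                    group_of[sibs[int(rng.integers(len(sibs)))]] = dest

        for i in alive:
            membership[(i, year)] = group_of[i]

    # --- assemble outputs ---------------------------------------------------
    records = [
        PedigreeRecord(i, dam=parents[i][0], sire=parents[i][1], sex=sex[i])
        for i in sorted(sex)
    ]
    ped = validate_pedigree(records)

    tenures: list[AlphaTenure] = []
    for g in groups:
        seq = [(y, a) for (gg, y, a) in alpha_years if gg == g]
        start_y, cur = seq[0]
        prev_y = start_y
        for y, a in seq[1:]:
            if a != cur:
                tenures.append(AlphaTenure(g, cur, (start_y, 1), (prev_y, 12)))
                start_y, cur = y, a
            prev_y = y
        tenures.append(AlphaTenure(g, cur, (start_y, 1), (prev_y, 12)))

    return Population(
        pedigree=ped, tenures=tenures, membership=membership, birthdate=birth, sex=sex
    )


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def simulate_breeding_values(
    ped: Pedigree, sigma_a2: float, seed: int = 0
) -> dict[str, float]:
    """Draw additive genetic values down the pedigree.

    Founders are N(0, sigma_A^2); offspring get the parental average plus a
    Mendelian deviation whose variance is deflated by parental inbreeding
    (unknown parents contribute zero with compensating variance), so that
    Cov(a) = sigma_A^2 * A exactly.
    """
    if sigma_a2 < 0:
        raise ValueError("sigma_a2 must be >= 0")
    rng = np.random.default_rng(seed)
    if sigma_a2 == 0.0:
        return {i: 0.0 for i in ped.ids}
    rel = additive_relationship_matrix(ped)
    F = dict(zip(rel.ids, rel.F))
    values: dict[str, float] = {}
    for rec in ped.records:  # topological order
        mean = 0.0
        var = sigma_a2
        for p in (rec.dam, rec.sire):
            if p is not None:
                mean += 0.5 * values[p]
                var -= 0.25 * sigma_a2 * (1.0 + F[p])
        values[rec.id] = mean + rng.normal(0.0, np.sqrt(max(var, 0.0)))
    return values


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

def simulate_observations(
    pop: Population, params: TrueParameters, seed: int = 0
) -> SyntheticDataset:
    """Generate filtered monthly records from the latent decomposition.

    Subject-months are sampled for individuals at least one year old with a
    scan count drawn from a truncated Poisson (minimum five); records are
    passed through the default inclusion filters, the fixed-effect design is
    built on the surviving records (z-scores from the realized sample), and
    responses are drawn from eta = x'beta + sum(u) + e for both families.
    """
    rng = np.random.default_rng(seed)
    years = range(params.first_year, params.first_year + params.n_years)
    months = [(y, m) for y in years for m in range(1, 13)]

    # climate index: AR(1) with the stationary SD chosen so roughly a quarter
    # of months leave the neutral band
    mei = {}
    x = rng.normal(0.0, params.mei_sd)
    innov_sd = params.mei_sd * np.sqrt(1.0 - params.mei_phi**2)
    for ym in months:
        x = params.mei_phi * x + rng.normal(0.0, innov_sd)
        mei[ym] = x

    alpha_at = {}
    for t in pop.tenures:
        for y in range(t.start[0], t.end[0] + 1):
            alpha_at[(t.group, y)] = t.alpha_male

    group_size = {}
    for (i, y), g in pop.membership.items():
        group_size[(g, y)] = group_size.get((g, y), 0) + 1

    raw: list[MonthlyRecord] = []
    for i in sorted(pop.sex):
        by, bm = pop.birthdate[i]
        for y, m in months:
            g = pop.membership.get((i, y))
            if g is None:
                continue
            age = (y - by) + (m - bm) / 12.0
            if age < 1.0:
                continue
            if rng.random() >= params.obs_prob:
                continue
            n_scans = max(params.min_scans, int(rng.poisson(params.mean_scans)))
            raw.append(
                MonthlyRecord(
                    subject=i,
                    year=y,
                    month=m,
                    group=g,
                    alpha=alpha_at[(g, y)],
                    n_scans=n_scans,
                    n_social=0,
                    total_partners=0,
                    age_years=age,
                    sex=pop.sex[i],
                    group_size=float(group_size[(g, y)]),
                    mei=float(mei[(y, m)]),
                    mother=pop.pedigree.dam_of(i),
                )
            )

    records = filter_records(raw)
    if not records:
        raise RuntimeError("no records survive the inclusion filters")

    design = build_design(records, DesignSpec())
    beta = np.array([params.beta.get(c, 0.0) for c in design.columns])
    eta = design.X @ beta

    v = params.variances
    realized: dict[str, dict] = {}
    keys = design.group_keys
    for term in keys.columns:
        if term == "animal":
            bv = simulate_breeding_values(
                pop.pedigree, v["animal"], seed=int(rng.integers(2**31))
            )
            realized[term] = bv
            eta = eta + np.array([bv[s] for s in keys["animal"]])
        else:
            levels = sorted(keys[term].unique())
            draws = rng.normal(0.0, np.sqrt(v[term]), size=len(levels))
            lut = dict(zip(levels, draws))
            realized[term] = lut
            eta = eta + keys[term].map(lut).to_numpy(float)
    resid = rng.normal(0.0, np.sqrt(v["residual"]), size=len(records))
    eta = eta + resid
    realized["residual"] = resid

    n_scans = np.array([r.n_scans for r in records])
    p_social = 1.0 / (1.0 + np.exp(-eta))
    n_social = rng.binomial(n_scans, p_social)
    partners = rng.poisson(n_scans * np.exp(eta))
    for r, ns, tp in zip(records, n_social, partners):
        r.n_social = int(ns)
        r.total_partners = int(max(tp, ns))  # at least one partner per social scan

    # rebuild the design so the records frame carries the final responses
    design = build_design(records, DesignSpec())
    return SyntheticDataset(
        population=pop, records=records, truth=params, realized=realized, design=design
    )


def make_dataset(
    params: TrueParameters | None = None, seed: int = 0
) -> SyntheticDataset:
    """Convenience wrapper: population + observations from one seed."""
    params = params if params is not None else TrueParameters()
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    pop = simulate_population(params, seed=int(ss[0]))
    return simulate_observations(pop, params, seed=int(ss[1]))
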