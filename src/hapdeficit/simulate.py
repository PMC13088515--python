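"""Forward simulation of a closed horse population segregating a recessive lethal.

The generator produces the inputs the downstream analysis consumes without any
external data: a multi-generation pedigree with a popular-sire mating
structure, phased chip-density genotypes realized by gene drop of founder
haplotypes with one crossover per meiosis, a planted lethal haplotype whose
causal variant is an off-chip locus in near-complete LD with it, and mating /
foal-registration records whose statistical structure (baseline insemination
success, re-matings within 10 days, incomplete registration) mirrors studbook
breeding data.

Dates are integer day offsets from an arbitrary epoch (2000-01-01 when
rendered to CSV); gestation is fixed at 340 days, a horse-typical constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import PhasedGenotypes, write_marker_map, write_vcf

EPOCH = pd.Timestamp("2000-01-01")
GESTATION_DAYS = 340
GENERATION_GAP_DAYS = 1825  # ~5 years between cohorts
MIN_BREEDING_AGE_DAYS = 1100
MAX_BREEDING_AGE_DAYS = 7300
ESTRUS_CYCLE_DAYS = 21
POPULAR_SIRE_SHARE = 0.7  # mating share funnelled to the top sires
# Conditional extra failure rate of carrier x carrier conceptions under full
# embryonic lethality: 1/4 of conceptions are homozygous and die.
EMBRYONIC_LOSS_FRACTION = 0.25

PENETRANCE_STAGES = ("embryonic", "stillbirth", "juvenile", "none")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population.

    Defaults describe a closed studbook population: a lethal haplotype at
    founder frequency 0.07 (carrier frequency ~13%, mid-range of the 8-22%
    band observed for drift-borne lethals), baseline per-cycle insemination
    success of 0.65, and chip-density markers (one per ~50 kb).
    """

    n_founders: int = 400
    n_generations: int = 5
    popular_sire_fraction: float = 0.1
    n_markers: int = 480
    genome_length_bp: int = 24_000_000
    q_lethal: float = 0.07
    penetrance_stage: str = "embryonic"
    baseline_insemination_success: float = 0.65
    baseline_stillbirth: float = 0.03
    baseline_juvenile_mortality: float = 0.04
    remating_prob: float = 0.3
    registration_completeness: float = 0.9
    rng_seed: int = 0
    # -- secondary knobs ---------------------------------------------------
    n_offspring_per_generation: int | None = None  # default: n_founders
    chrom: str = "1"
    lethal_region_length_bp: int = 1_500_000
    #: probability a founder chromosome carries the full lethal haplotype but
    #: not the causal variant (ancestral recombination breaking their LD)
    causal_ld_breakage: float = 0.02

    def __post_init__(self) -> None:
        if self.n_offspring_per_generation is None:
            self.n_offspring_per_generation = self.n_founders
        probs = {
            "popular_sire_fraction": self.popular_sire_fraction,
            "baseline_insemination_success": self.baseline_insemination_success,
            "baseline_stillbirth": self.baseline_stillbirth,
            "baseline_juvenile_mortality": self.baseline_juvenile_mortality,
            "remating_prob": self.remating_prob,
            "registration_completeness": self.registration_completeness,
            "causal_ld_breakage": self.causal_ld_breakage,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 < self.q_lethal < 0.5:
            raise ValueError("q_lethal must be in (0, 0.5)")
        if self.n_markers < 2:
            raise ValueError("n_markers must be >= 2")
        if self.genome_length_bp < 2_000_000:
            raise ValueError("genome_length_bp must be >= 2,000,000 (one 2-Mb window)")
        if self.penetrance_stage not in PENETRANCE_STAGES:
            raise ValueError(f"penetrance_stage must be one of {PENETRANCE_STAGES}")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.lethal_region_length_bp < 1_000_000:
            raise ValueError("lethal region must span at least 1 Mb")
        if self.lethal_region_length_bp > self.genome_length_bp:
            raise ValueError("lethal region longer than the genome")


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    """Independent, reproducible stream per pipeline stage from one seed."""
    return np.random.default_rng([stage, config.rng_seed])


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

PEDIGREE_COLUMNS = [
    "animal_id", "sire_id", "dam_id", "birth_date", "sex",
    "generation", "dead_at_birth", "death_date",
]


def validate_pedigree(pedigree: pd.DataFrame) -> None:
    """Assert pedigree invariants: sexes, parental birth order, acyclicity."""
    missing = [c for c in ("animal_id", "sire_id", "dam_id", "birth_date", "sex")
               if c not in pedigree.columns]
    if missing:
        raise ValueError(f"pedigree missing columns: {missing}")
    if pedigree["animal_id"].duplicated().any():
        raise ValueError("duplicate animal ids in pedigree")
    sex = dict(zip(pedigree["animal_id"], pedigree["sex"]))
    birth = dict(zip(pedigree["animal_id"], pedigree["birth_date"]))
    for row in pedigree.itertuples(index=False):
        for parent, want in ((row.sire_id, "M"), (row.dam_id, "F")):
            if not parent:
                continue
            if parent == row.animal_id:
                raise ValueError(f"{row.animal_id} is its own parent")
            if parent in sex and sex[parent] != want:
                raise ValueError(f"parent {parent} has wrong sex for its role")
            if parent in birth and birth[parent] >= row.birth_date:
                raise ValueError(f"parent {parent} not born before {row.animal_id}")
    # Parents precede offspring in birth date, so birth order is a topological
    # order and the parent-offspring graph cannot contain a cycle.


def simulate_pedigree(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a multi-generation pedigree with a popular-sire mating structure.

    The top ``popular_sire_fraction`` of breeding sires in each cohort receive
    a fixed 70% share of the matings; the remainder is spread uniformly.
    Baseline (non-genetic) stillbirths and juvenile deaths are drawn here so
    that dead animals are never chosen as parents.
    """
    if config.n_generations < 2:
        raise ValueError("n_generations must be >= 2 (no matings possible)")
    rng = _stage_rng(config, 1)
    n_off = int(config.n_offspring_per_generation)

    counter = 0

    def new_ids(n: int) -> list[str]:
        nonlocal counter
        ids = [f"A{counter + i + 1:06d}" for i in range(n)]
        counter += n
        return ids

    records: list[dict] = []
    founder_ids = new_ids(config.n_founders)
    founder_sex = np.where(np.arange(config.n_founders) % 2 == 0, "M", "F")
    rng.shuffle(founder_sex)
    for i, aid in enumerate(founder_ids):
        records.append(dict(
            animal_id=aid, sire_id="", dam_id="",
            birth_date=int(rng.integers(0, 365)), sex=str(founder_sex[i]),
            generation=0, dead_at_birth=False, death_date=np.nan,
        ))

    frame = pd.DataFrame.from_records(records)
    for g in range(1, config.n_generations):
        births = g * GENERATION_GAP_DAYS + rng.integers(0, 365, size=n_off)
        conceptions = births - GESTATION_DAYS
        ref_date = int(conceptions.min())
        age = ref_date - frame["birth_date"].to_numpy()
        alive = (~frame["dead_at_birth"].to_numpy()) & frame["death_date"].isna().to_numpy()
        eligible = alive & (age >= MIN_BREEDING_AGE_DAYS) & (age <= MAX_BREEDING_AGE_DAYS)
        males = frame.loc[eligible & (frame["sex"] == "M").to_numpy(), "animal_id"].to_numpy()
        females = frame.loc[eligible & (frame["sex"] == "F").to_numpy(), "animal_id"].to_numpy()
        if len(males) == 0 or len(females) == 0:
            raise ValueError(f"no eligible breeding animals for generation {g}")

        weights = _popular_sire_weights(len(males), config.popular_sire_fraction, rng)
        sires = rng.choice(males, size=n_off, p=weights)
        dams = rng.choice(females, size=n_off)
        child_ids = new_ids(n_off)
        child_sex = rng.choice(np.array(["M", "F"]), size=n_off)

        stillborn = rng.random(n_off) < config.baseline_stillbirth
        juv = (~stillborn) & (rng.random(n_off) < config.baseline_juvenile_mortality)
        death_day = rng.integers(0, 366, size=n_off)

        cohort = []
        for i in range(n_off):
            death = np.nan
            if stillborn[i]:
                death = float(births[i])
            elif juv[i]:
                death = float(births[i] + death_day[i])
            cohort.append(dict(
                animal_id=child_ids[i], sire_id=str(sires[i]), dam_id=str(dams[i]),
                birth_date=int(births[i]), sex=str(child_sex[i]), generation=g,
                dead_at_birth=bool(stillborn[i]), death_date=death,
            ))
        frame = pd.concat([frame, pd.DataFrame.from_records(cohort)], ignore_index=True)
    return frame


def _popular_sire_weights(n_males: int, fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    if n_males == 1 or fraction <= 0 or fraction >= 1:
        return np.full(n_males, 1.0 / n_males)
    n_top = max(1, int(np.ceil(fraction * n_males)))
    if n_top >= n_males:
        return np.full(n_males, 1.0 / n_males)
    order = rng.permutation(n_males)
    weights = np.empty(n_males)
    weights[order[:n_top]] = POPULAR_SIRE_SHARE / n_top
    weights[order[n_top:]] = (1.0 - POPULAR_SIRE_SHARE) / (n_males - n_top)
    return weights


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------


@dataclass
class TrueState:
    """Ground truth of the planted lethal: region, causal genotypes, removals."""

    chrom: str
    region_start: int  # bp, half-open [start, end)
    region_end: int
    causal_pos: int
    region_marker_idx: np.ndarray
    lethal_alleles: np.ndarray  # allele string of the lethal haplotype over region markers
    #: per conceived animal: (hap copy carries full lethal string x2, causal allele x2)
    causal_genotype: dict[str, int] = field(default_factory=dict)
    hap_carrier_copies: dict[str, tuple[int, int]] = field(default_factory=dict)
    embryonic_losses: pd.DataFrame = field(default_factory=pd.DataFrame)
    cascade_removed: list[str] = field(default_factory=list)
    #: gene-drop fate overrides: animal -> ("stillbirth"|"juvenile", death_date)
    lethal_fates: dict[str, tuple[str, int]] = field(default_factory=dict)
    genotyped_animals: list[str] = field(default_factory=list)

    @property
    def carriers(self) -> list[str]:
        return [a for a in self.genotyped_animals if self.causal_genotype.get(a) == 1]

    def to_json_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "region_start": int(self.region_start),
            "region_end": int(self.region_end),
            "causal_pos": int(self.causal_pos),
            "lethal_alleles": "".join(map(str, self.lethal_alleles.tolist())),
            "n_embryonic_losses": int(len(self.embryonic_losses)),
            "n_cascade_removed": len(self.cascade_removed),
            "carriers": self.carriers,
        }


def make_marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Uniformly spaced diallelic markers over one chromosome, 1-based positions."""
    spacing = config.genome_length_bp / config.n_markers
    pos = (np.arange(config.n_markers) * spacing + spacing / 2).astype(np.int64) + 1
    return pd.DataFrame({
        "chrom": config.chrom,
        "marker_id": [f"M{i + 1:06d}" for i in range(config.n_markers)],
        "pos_bp": pos,
        "allele1": "A",
        "allele2": "B",
    })


def planted_region(config: SimulationConfig) -> tuple[int, int, int]:
    """(start, end, causal_pos) of the lethal region, centred on the chromosome."""
    start = (config.genome_length_bp - config.lethal_region_length_bp) // 2
    end = start + config.lethal_region_length_bp
    return start, end, (start + end) // 2


def gene_drop(pedigree: pd.DataFrame, config: SimulationConfig
              ) -> tuple[PhasedGenotypes, TrueState]:
    """Drop founder haplotypes through the pedigree with one crossover per meiosis.

    Founder chromosomes carry the lethal haplotype (all-'1' alleles over the
    planted region) with probability ``q_lethal``; the causal variant is a
    separate off-chip locus at the region centre riding on the same
    chromosome, minus rare founder-level LD breakage.  Homozygosity for the
    causal variant is resolved according to ``penetrance_stage``: conceptions
    die in utero (embryonic), foals are born dead (stillbirth), or die within
    the first year (juvenile).  Offspring of animals removed by lethality are
    cascade-removed (those conceptions never happened).

    Returns phased genotypes of the *genotyped* animals — survivors, since an
    animal must live to be sampled — plus the full ground truth.
    """
    rng = _stage_rng(config, 2)
    markers = make_marker_map(config)
    pos = markers["pos_bp"].to_numpy()
    m = config.n_markers
    start, end, causal_pos = planted_region(config)
    region_idx = np.flatnonzero((pos >= start) & (pos < end))
    if len(region_idx) < 2:
        raise ValueError("planted region covers fewer than 2 markers")
    lethal_alleles = np.ones(len(region_idx), dtype=np.uint8)

    if 2 * config.n_founders * config.q_lethal < 1:
        raise ValueError(
            "q_lethal implies zero carrier chromosomes among the founders; "
            "increase n_founders or q_lethal")

    freqs = rng.uniform(0.05, 0.95, size=m)
    ped = pedigree.sort_values(["birth_date", "animal_id"], kind="stable")

    haplo: dict[str, np.ndarray] = {}         # animal -> (2, M) uint8
    causal: dict[str, np.ndarray] = {}        # animal -> (2,) uint8
    state = TrueState(config.chrom, start, end, causal_pos, region_idx, lethal_alleles)
    removed: set[str] = set()
    losses: list[dict] = []

    L = config.genome_length_bp

    def gamete(parent: str) -> tuple[np.ndarray, int]:
        h = haplo[parent]
        c = causal[parent]
        x = rng.uniform(0, L)
        first = int(rng.integers(0, 2))
        out = np.where(pos < x, h[first], h[1 - first])
        c_out = int(c[first] if causal_pos < x else c[1 - first])
        return out.astype(np.uint8), c_out

    for row in ped.itertuples(index=False):
        aid = row.animal_id
        if not row.sire_id and not row.dam_id:
            # Founders are living adults: under any lethal penetrance stage a
            # causal-homozygous founder would have died before breeding, so
            # the draw is conditioned on not being homozygous.
            while True:
                h = (rng.random((2, m)) < freqs).astype(np.uint8)
                c = np.zeros(2, dtype=np.uint8)
                for copy in range(2):
                    if rng.random() < config.q_lethal:
                        h[copy, region_idx] = lethal_alleles
                        c[copy] = 0 if rng.random() < config.causal_ld_breakage else 1
                if c.sum() < 2 or config.penetrance_stage == "none":
                    break
            haplo[aid] = h
            causal[aid] = c
        else:
            if row.sire_id in removed or row.dam_id in removed:
                removed.add(aid)
                state.cascade_removed.append(aid)
                continue
            hs, cs = gamete(row.sire_id)
            hd, cd = gamete(row.dam_id)
            haplo[aid] = np.stack([hs, hd])
            causal[aid] = np.array([cs, cd], dtype=np.uint8)
            if cs + cd == 2:
                stage = config.penetrance_stage
                if stage == "embryonic":
                    removed.add(aid)
                    losses.append(dict(animal_id=aid, sire_id=row.sire_id,
                                       dam_id=row.dam_id,
                                       conception_date=int(row.birth_date) - GESTATION_DAYS))
                    continue
                if stage == "stillbirth":
                    removed.add(aid)  # dead at birth: never a parent, never genotyped
                    state.lethal_fates[aid] = ("stillbirth", int(row.birth_date))
                elif stage == "juvenile":
                    removed.add(aid)
                    death = int(row.birth_date) + int(rng.integers(0, 365))
                    state.lethal_fates[aid] = ("juvenile", death)
        state.causal_genotype[aid] = int(causal[aid].sum())
        hap_flags = tuple(
            int(np.array_equal(haplo[aid][copy, region_idx], lethal_alleles))
            for copy in range(2))
        state.hap_carrier_copies[aid] = hap_flags

    state.embryonic_losses = pd.DataFrame(
        losses, columns=["animal_id", "sire_id", "dam_id", "conception_date"])

    # Genotyped = survivors: born alive, not dead before sampling.
    ped_alive = ped[~ped["animal_id"].isin(removed)
                    & ~ped["dead_at_birth"].astype(bool)
                    & ped["death_date"].isna()]
    genotyped = ped_alive["animal_id"].tolist()
    state.genotyped_animals = genotyped
    alleles = np.stack([haplo[a] for a in genotyped]).transpose(0, 2, 1)  # (N, M, 2)
    phased = PhasedGenotypes(genotyped, alleles, markers)
    return phased, state


def prune_pedigree(pedigree: pd.DataFrame, state: TrueState) -> pd.DataFrame:
    """Pedigree of animals actually born, with gene-drop fates applied."""
    removed = set(state.embryonic_losses["animal_id"]) | set(state.cascade_removed)
    out = pedigree[~pedigree["animal_id"].isin(removed)].copy()
    for aid, (kind, death) in state.lethal_fates.items():
        sel = out["animal_id"] == aid
        if not sel.any():
            continue
        out.loc[sel, "death_date"] = float(death)
        if kind == "stillbirth":
            out.loc[sel, "dead_at_birth"] = True
    return out


# ---------------------------------------------------------------------------
# Mating and foal records
# ---------------------------------------------------------------------------


def simulate_matings(pedigree: pd.DataFrame, state: TrueState,
                     config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive mating and foal-registration records from the realized pedigree.

    Every realized conception (a born foal, or an embryonic loss) is one
    successful insemination *event*; insemination failures preceding it are
    drawn geometrically with per-cycle success ``baseline_insemination_success``
    and placed one estrus cycle (21 d) apart.  A failed event spawns a
    duplicate re-mating record 1-10 days later with probability
    ``remating_prob`` (same event: re-inseminations within one cycle do not
    get an independent conception chance).  Each mating row is finally written
    with probability ``registration_completeness``; foal registration is kept
    complete, so an unregistered successful mating leaves an orphan foal.
    """
    rng = _stage_rng(config, 3)
    b = config.baseline_insemination_success
    ped = prune_pedigree(pedigree, state)

    foals = ped[ped["generation"] > 0] if "generation" in ped.columns else \
        ped[(ped["sire_id"] != "") | (ped["dam_id"] != "")]
    foal_rows = pd.DataFrame({
        "foal_id": foals["animal_id"].to_numpy(),
        "dam_id": foals["dam_id"].to_numpy(),
        "sire_id": foals["sire_id"].to_numpy(),
        "birth_date": foals["birth_date"].to_numpy(),
        "dead_at_birth": foals["dead_at_birth"].astype(int).to_numpy(),
        "death_date": foals["death_date"].to_numpy(),
    })

    events = [  # (sire, dam, date, succeeded)
        (r.sire_id, r.dam_id, int(r.birth_date) - GESTATION_DAYS, True)
        for r in foals.itertuples(index=False)
    ]
    events += [
        (r.sire_id, r.dam_id, int(r.conception_date), False)
        for r in state.embryonic_losses.itertuples(index=False)
    ]

    mating_rows: list[tuple[str, str, int]] = []
    for sire, dam, date, _success in events:
        n_fail = int(rng.geometric(b)) - 1 if b < 1 else 0
        for i in range(min(n_fail, 20)):
            fail_date = date - ESTRUS_CYCLE_DAYS * (i + 1)
            mating_rows.append((sire, dam, fail_date))
            if rng.random() < config.remating_prob:
                mating_rows.append((sire, dam, fail_date + int(rng.integers(1, 11))))
        mating_rows.append((sire, dam, date))
        if not _success and rng.random() < config.remating_prob:
            mating_rows.append((sire, dam, date + int(rng.integers(1, 11))))

    matings = pd.DataFrame(mating_rows, columns=["sire_id", "dam_id", "date"])
    if config.registration_completeness < 1:
        keep = rng.random(len(matings)) < config.registration_completeness
        matings = matings[keep]
    matings = matings.sort_values(["date", "sire_id", "dam_id"],
                                  kind="stable").reset_index(drop=True)
    return matings, foal_rows


def simulate_mating_cohort(config: SimulationConfig, n_pairs: int,
                           sire_carrier: bool, dam_carrier: bool,
                           rng: np.random.Generator,
                           id_prefix: str = "C") -> tuple[pd.DataFrame, pd.DataFrame,
                                                          pd.DataFrame]:
    """Simulate one insemination event per pair for a fixed-genotype cohort.

    Used to measure fertility contrasts at a chosen number of matings: each
    pair is (carrier or non-carrier sire) x carrier dam, the conception is
    drawn mechanistically from parental causal genotypes, and homozygous
    conceptions die in utero under embryonic penetrance.  Returns matings,
    foals, and a carrier-status table for the parents.
    """
    b = config.baseline_insemination_success
    sires = [f"{id_prefix}S{i + 1:06d}" for i in range(n_pairs)]
    dams = [f"{id_prefix}D{i + 1:06d}" for i in range(n_pairs)]
    dates = rng.integers(2000, 4000, size=n_pairs)

    inseminated = rng.random(n_pairs) < b
    sire_allele = (rng.random(n_pairs) < 0.5).astype(int) if sire_carrier else \
        np.zeros(n_pairs, dtype=int)
    dam_allele = (rng.random(n_pairs) < 0.5).astype(int) if dam_carrier else \
        np.zeros(n_pairs, dtype=int)
    hom = (sire_allele + dam_allele) == 2
    lethal = hom & (config.penetrance_stage == "embryonic")
    success = inseminated & ~lethal

    mating_rows = []
    foal_rows = []
    for i in range(n_pairs):
        mating_rows.append((sires[i], dams[i], int(dates[i])))
        if not success[i]:
            if rng.random() < config.remating_prob:
                mating_rows.append((sires[i], dams[i],
                                    int(dates[i]) + int(rng.integers(1, 11))))
            continue
        birth = int(dates[i]) + GESTATION_DAYS
        dead = rng.random() < config.baseline_stillbirth
        death = np.nan
        if dead:
            death = float(birth)
        elif rng.random() < config.baseline_juvenile_mortality:
            death = float(birth + int(rng.integers(0, 366)))
        foal_rows.append((f"{id_prefix}F{i + 1:06d}", dams[i], sires[i],
                          birth, int(dead), death))

    matings = pd.DataFrame(mating_rows, columns=["sire_id", "dam_id", "date"])
    if config.registration_completeness < 1:
        keep = rng.random(len(matings)) < config.registration_completeness
        matings = matings[keep].reset_index(drop=True)
    foals = pd.DataFrame(foal_rows, columns=[
        "foal_id", "dam_id", "sire_id", "birth_date", "dead_at_birth", "death_date"])
    status = pd.DataFrame({
        "animal_id": sires + dams,
        "status": (["carrier" if sire_carrier else "non-carrier"] * n_pairs
                   + ["carrier" if dam_carrier else "non-carrier"] * n_pairs),
    })
    return matings, foals, status


# ---------------------------------------------------------------------------
# Sequenced-sire variant calls
# ---------------------------------------------------------------------------


def simulate_variant_calls(phased: PhasedGenotypes, state: TrueState,
                           config: SimulationConfig, *,
                           n_sequenced: int = 20,
                           n_neutral: int = 200,
                           rng: np.random.Generator | None = None):
    """Emulate variant calls for a panel of sequenced sires.

    Selects up to ``n_sequenced`` living males, biased to include the
    region's carriers, and emits (variants, carrier_flags): the planted
    causal variant — a frameshift deletion at the region centre whose
    genotypes come from the ground truth — plus ``n_neutral`` background
    variants with genotypes drawn independently of carrier status
    (Hardy-Weinberg at a random allele frequency), annotated with a mixture
    of consequence classes.  Returns :class:`~hapdeficit.prioritize.VariantRecord`
    objects plus the per-sire carrier flags used downstream.
    """
    from .prioritize import VariantRecord

    if rng is None:
        rng = _stage_rng(config, 4)
    genotyped = set(state.genotyped_animals)
    carriers = [a for a in state.carriers if a in genotyped]
    noncarriers = [a for a in genotyped
                   if state.causal_genotype.get(a) == 0]
    n_car = min(len(carriers), max(2, n_sequenced // 3))
    seq_carriers = list(rng.choice(carriers, size=n_car, replace=False)) \
        if n_car else []
    n_non = min(len(noncarriers), n_sequenced - n_car)
    seq_non = list(rng.choice(noncarriers, size=n_non, replace=False))
    sires = [str(s) for s in seq_carriers + seq_non]
    carrier_flags = {s: state.causal_genotype.get(s, 0) >= 1 for s in sires}

    causal = VariantRecord(
        chrom=state.chrom, pos=state.causal_pos,
        ref="CCACCATGAACACTG", alt="C", var_class="indel",
        consequence="GENE1|frameshift|p.423fs",
        genotypes={s: int(state.causal_genotype.get(s, 0)) for s in sires})

    variants = [causal]
    classes = ["intron", "synonymous", "missense", "intergenic"]
    for i in range(n_neutral):
        pos = int(rng.integers(1, config.genome_length_bp))
        af = float(rng.uniform(0.05, 0.5))
        draws = rng.random((len(sires), 2)) < af
        gts = {s: int(draws[j].sum()) for j, s in enumerate(sires)}
        cls = classes[int(rng.integers(0, len(classes)))]
        sift = float(np.round(rng.uniform(0, 1), 3)) if cls == "missense" else None
        variants.append(VariantRecord(
            chrom=state.chrom, pos=pos, ref="A", alt="G", var_class="SNP",
            consequence=f"GENE{i + 2}|{cls}|", sift=sift, genotypes=gts))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants, carrier_flags


def write_variant_vcf(variants, carrier_flags: dict[str, bool],
                      config: SimulationConfig, path: str | Path) -> None:
    """Write simulated sequenced-sire variants as an annotated VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "hapdeficit-simulate")
    header.contigs.add(config.chrom, length=config.genome_length_bp + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("CSQ", 1, "String", "Consequence annotation gene|class|change")
    header.info.add("SIFT", 1, "Float", "SIFT score")
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("END", 1, "Integer", "SV end position")
    sires = sorted(carrier_flags)
    for s in sires:
        header.add_sample(s)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            if v.consequence:
                rec.info["CSQ"] = v.consequence
            if v.sift is not None:
                rec.info["SIFT"] = v.sift
            if v.var_class == "SV":
                rec.info["SVTYPE"] = "DEL"
                rec.info["END"] = v.sv_end
            for s in sires:
                g = v.genotypes.get(s, -1)
                rec.samples[s]["GT"] = gt_codes.get(g, (None, None))
            out.write(rec)


# ---------------------------------------------------------------------------
# Chip emulation (file outputs)
# ---------------------------------------------------------------------------


def emulate_chip(phased: PhasedGenotypes, out_dir: str | Path,
                 prefix: str = "genotypes") -> tuple[Path, Path]:
    """Write phased genotypes as a '|'-phased VCF plus a marker-map TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{prefix}.vcf"
    map_path = out_dir / f"{prefix}.map.tsv"
    write_vcf(phased, vcf_path)
    write_marker_map(phased.markers, map_path)
    return vcf_path, map_path


def days_to_date(days) -> pd.Series:
    """Render integer day offsets as calendar dates for CSV output."""
    offsets = pd.to_timedelta(np.asarray(days, dtype="float64"), unit="D")
    return pd.Series(EPOCH + offsets)


@dataclass
class SimulationResult:
    config: SimulationConfig
    pedigree: pd.DataFrame
    phased: PhasedGenotypes
    true_state: TrueState
    matings: pd.DataFrame
    foals: pd.DataFrame


def simulate_population(config: SimulationConfig) -> SimulationResult:
    """Run pedigree -> gene drop -> matings as one reproducible pass."""
    pedigree = simulate_pedigree(config)
    phased, state = gene_drop(pedigree, config)
    matings, foals = simulate_matings(pedigree, state, config)
    return SimulationResult(config, pedigree, phased, state, matings, foals)


def config_from_dict(d: dict) -> SimulationConfig:
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown simulation config fields: {sorted(unknown)}")
    return SimulationConfig(**d)
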