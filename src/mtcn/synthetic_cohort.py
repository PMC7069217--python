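"""Synthetic three-generation cohort generator.

Produces pedigree-structured participants with latent relative copy
numbers, qPCR plate tables with controlled threshold/batch/concentration
effect sizes, Poisson depth profiles, haplogroup-structured haploid mtDNA
genotypes, PCL-C responses and blood counts — everything the downstream
quantification and association stages consume, with known ground truth.

Latent copy number is log-normal: all effects are additive on the log
scale, so positivity is automatic and one ddCT cycle corresponds to one
two-fold change of template.

Randomness: one global seed feeds a fixed counter-based substream per
operation (cohort=1, qpcr=2, depth=3, genotypes=4, phenotypes=5), so adding
an operation never perturbs another's draws and identical config+seed
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mito_popgen import HaploidGenotypeMatrix
from .wgs_quant import DepthProfile

__all__ = [
    "CohortConfig",
    "CohortConfigError",
    "MT_LENGTH",
    "simulate_cohort",
    "simulate_qpcr_plates",
    "simulate_depth_profiles",
    "simulate_mtdna_genotypes",
    "simulate_phenotypes",
    "write_participants_csv",
    "write_plates_csv",
    "write_haplogroups_csv",
    "write_pclc_csv",
    "write_blood_csv",
]

MT_LENGTH = 16_569  # rCRS mitochondrial genome length
N_PCLC_ITEMS = 17

_STREAMS = {"cohort": 1, "qpcr": 2, "depth": 3, "genotypes": 4, "phenotypes": 5}

GENERATIONS = ("G1", "G2", "G3")
GROUPS = ("HS", "CTRL")


class CohortConfigError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


def _default_group_sizes() -> dict[str, int]:
    # "<generation>/<group>" keys keep the config YAML/JSON friendly.
    return {"G1/HS": 15, "G1/CTRL": 22, "G2/HS": 60, "G2/CTRL": 37,
            "G3/HS": 42, "G3/CTRL": 20}


def _default_age_params() -> dict[str, tuple[float, float, float, float]]:
    # (mean, sd, low, high) in years per generation
    return {"G1": (85.0, 4.0, 75.0, 99.0),
            "G2": (52.0, 10.0, 30.0, 73.0),
            "G3": (30.0, 8.0, 15.0, 48.0)}


def _default_ptsd_prevalence() -> dict[str, float]:
    return {"G1/HS": 0.47, "G1/CTRL": 0.10, "G2/HS": 0.30, "G2/CTRL": 0.11,
            "G3/HS": 0.21, "G3/CTRL": 0.12}


def _default_haplogroup_freqs() -> dict[str, float]:
    return {"H": 0.40, "U": 0.20, "J": 0.15, "L": 0.15, "M": 0.10}


def _default_blood_sex_effects() -> dict[str, float]:
    # effect of being male, in SD units of the measure
    return {"RBC_x10.12_per_L": 0.857, "HGB_g_per_L": 1.087,
            "HCT_L_per_L": 1.067, "MONO_percent": 0.955}


@dataclass
class CohortConfig:
    """Everything the simulator needs.  All counts and effect sizes are
    explicit so tests can switch individual mechanisms on and off."""

    # cohort structure
    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    male_fraction: float = 77 / 196
    age_params: dict[str, tuple] = field(default_factory=_default_age_params)
    linked_fraction: float = 0.35     # share of G2/G3 with recorded parents
    father_link_fraction: float = 0.6  # of linked children, share with a father id
    max_children_per_mother: int = 4
    dropout_rate: float = 0.0

    # latent copy number (log scale)
    group_beta: float = 0.0        # effect of maternal HS lineage
    age_slope: float = 0.0         # per year
    sex_beta: float = 0.0          # effect of being male
    maternal_h: float = 0.0        # transmission of the mother's deviation
    cn_noise_sd: float = 0.35
    dna_conc_mean: float = 50.0    # ng/uL, log-normal
    dna_conc_sd: float = 15.0

    # qPCR plate model
    n_plates: int = 17
    n_batches: int = 3
    wells_per_plate: int = 96
    sample_replicates: int = 2
    ref_replicates: int = 3
    variance_shares: tuple[float, float, float] = (0.45, 0.05, 0.01)
    well_noise_sd: float = 0.05
    plate_shift_sd: float = 0.3
    rnasep_base_ct: float = 25.0
    mt_cyb_base_ct: float = 20.0
    ntc_min_ct: float = 38.5
    ntc_contamination_rate: float = 0.02
    amplification_failure_rate: float = 0.02

    # depth model
    nuclear_depth: float = 30.0
    mt_depth_multiplier: float = 20.0
    nuclear_region_length: int = 20_000
    nuclear_region_name: str = "chr20"
    mt_region_name: str = "MT"

    # genotype model
    haplogroup_freqs: dict[str, float] = field(default_factory=_default_haplogroup_freqs)
    total_snps: int = 400
    defining_snps_per_haplogroup: int = 5
    private_snp_counts: dict[str, int] = field(default_factory=lambda: {"L": 30})
    private_carrier_rate: float = 0.3
    genotype_missing_rate: float = 0.0

    # phenotypes
    ptsd_prevalence: dict[str, float] = field(default_factory=_default_ptsd_prevalence)
    pclc_cutoff: int = 30
    pclc_item_range: tuple[int, int] = (0, 5)
    blood_subset_size: int = 70
    blood_sex_effects: dict[str, float] = field(default_factory=_default_blood_sex_effects)

    seed: int = 0

    def __post_init__(self):
        for key, n in self.group_sizes.items():
            gen, _, grp = key.partition("/")
            if gen not in GENERATIONS or grp not in GROUPS:
                raise CohortConfigError(f"bad group-size key {key!r}")
            if n < 0:
                raise CohortConfigError(f"negative count for {key}")
        shares = self.variance_shares
        if len(shares) != 3 or any(not (0 <= s <= 1) for s in shares):
            raise CohortConfigError("variance shares must be three values in [0,1]")
        if sum(shares) >= 1:
            raise CohortConfigError("variance shares must sum to < 1")
        if not (0 <= self.maternal_h <= 1):
            raise CohortConfigError("maternal_h must be in [0,1]")
        if not (0 <= self.dropout_rate < 1):
            raise CohortConfigError("dropout_rate must be in [0,1)")
        for cell, p in self.ptsd_prevalence.items():
            if not (0 <= p <= 1):
                raise CohortConfigError(f"PTSD prevalence {p} for {cell} outside [0,1]")
        if self.nuclear_depth <= 0:
            raise CohortConfigError("nuclear_depth must be > 0")
        if self.mt_depth_multiplier < 0:
            raise CohortConfigError("mt_depth_multiplier must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-operation substream of the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]]))

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise CohortConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("variance_shares", "pclc_item_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "age_params" in d:
            d["age_params"] = {k: tuple(v) for k, v in d["age_params"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# cohort + latent state


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate participants and their latent states.

    Returns ``(participants, latents)``: the participant table (id,
    generation, group, sex, age, mother_id, father_id, maternal_hs_lineage,
    dna_conc_ng_ul) and the latent table (id, true_cn, ptsd_severity).

    Latent log copy number is
    ``group_beta*I[maternal HS lineage] + age_slope*age + sex_beta*I[male]
    + h*(mother's deviation) + noise``; deviation means the mother's log CN
    minus her own fixed-effect part, so ``h=1`` with zero noise copies the
    mother's deviation exactly.
    """
    rng = config.rng("cohort")
    rows = []
    counter = 0
    for gen in GENERATIONS:
        for grp in GROUPS:
            n = config.group_sizes.get(f"{gen}/{grp}", 0)
            mean, sd, low, high = config.age_params[gen]
            ages = _truncated_normal(rng, mean, sd, low, high, n)
            n_male = int(round(config.male_fraction * n))
            sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
            rng.shuffle(sexes)
            for i in range(n):
                counter += 1
                rows.append({
                    "id": f"S{counter:04d}", "generation": gen, "group": grp,
                    "sex": sexes[i], "age": float(np.round(ages[i], 1)),
                    "mother_id": None, "father_id": None,
                })
    df = pd.DataFrame(rows)

    # pedigree: linked children draw a mother (and often a father) from the
    # previous generation of the same group, mothers reused up to the cap
    for gen_idx in (1, 2):
        gen, prev = GENERATIONS[gen_idx], GENERATIONS[gen_idx - 1]
        for grp in GROUPS:
            children = df.index[(df["generation"] == gen) & (df["group"] == grp)]
            n_linked = int(round(config.linked_fraction * len(children)))
            if n_linked == 0:
                continue
            mothers = df.loc[(df["generation"] == prev) & (df["group"] == grp)
                             & (df["sex"] == "F"), "id"].tolist()
            capacity = len(mothers) * config.max_children_per_mother
            if n_linked > capacity:
                raise CohortConfigError(
                    f"{gen}/{grp}: {n_linked} linked children exceed mother "
                    f"capacity {capacity}")
            fathers = df.loc[(df["generation"] == prev) & (df["group"] == grp)
                             & (df["sex"] == "M"), "id"].tolist()
            linked = rng.choice(children, size=n_linked, replace=False)
            slots = np.repeat(mothers, config.max_children_per_mother)
            slots = rng.permutation(slots)[:n_linked]
            for child_idx, mother in zip(linked, slots):
                df.at[child_idx, "mother_id"] = mother
                if fathers and rng.random() < config.father_link_fraction:
                    df.at[child_idx, "father_id"] = rng.choice(fathers)

    df["maternal_hs_lineage"] = [_maternal_hs(df, i) for i in df["id"]]
    conc_sigma = math.sqrt(math.log(1 + (config.dna_conc_sd / config.dna_conc_mean) ** 2))
    conc_mu = math.log(config.dna_conc_mean) - conc_sigma ** 2 / 2
    df["dna_conc_ng_ul"] = np.round(
        rng.lognormal(conc_mu, conc_sigma, size=len(df)), 2)

    # latent copy number, generation order so a mother's value exists first
    fixed, logcn = {}, {}
    severity = {}
    meta = df.set_index("id")
    for gen in GENERATIONS:
        for pid, row in meta[meta["generation"] == gen].iterrows():
            fx = (config.group_beta * float(row["maternal_hs_lineage"])
                  + config.age_slope * row["age"]
                  + config.sex_beta * float(row["sex"] == "M"))
            dev = 0.0
            mother = row["mother_id"]
            if mother is not None and config.maternal_h > 0:
                dev = config.maternal_h * (logcn[mother] - fixed[mother])
            noise = rng.normal(0.0, config.cn_noise_sd) if config.cn_noise_sd > 0 else 0.0
            fixed[pid] = fx
            logcn[pid] = fx + dev + noise
            prev = config.ptsd_prevalence.get(
                f"{row['generation']}/{row['group']}", 0.0)
            mu = stats.norm.ppf(np.clip(prev, 1e-12, 1 - 1e-12))
            if prev in (0.0, 1.0):
                mu = -np.inf if prev == 0.0 else np.inf
            severity[pid] = mu + rng.normal()

    latents = pd.DataFrame({
        "id": df["id"],
        "true_cn": [float(np.exp(logcn[i])) for i in df["id"]],
        "ptsd_severity": [severity[i] for i in df["id"]],
    })

    if config.dropout_rate > 0:
        keep = rng.random(len(df)) >= config.dropout_rate
        df, latents = df[keep].reset_index(drop=True), latents[keep].reset_index(drop=True)
    return df, latents


def _maternal_hs(df: pd.DataFrame, pid: str) -> bool:
    """True iff an unbroken mother chain from pid ends at a G1 HS member."""
    meta = df.set_index("id")
    seen = set()
    while True:
        if pid in seen:
            raise CohortConfigError("pedigree cycle detected")
        seen.add(pid)
        row = meta.loc[pid]
        if row["generation"] == "G1":
            return bool(row["group"] == "HS")
        mother = row["mother_id"]
        if mother is None or pd.isna(mother):
            return False
        pid = mother


# ---------------------------------------------------------------------------
# qPCR plates


def _well_labels(n: int) -> list[str]:
    rows = "ABCDEFGH"
    labels = [f"{r}{c}" for r in rows for c in range(1, 13)]
    while len(labels) < n:
        labels.append(f"X{len(labels) + 1}")
    return labels[:n]


def simulate_qpcr_plates(
    participants: pd.DataFrame,
    latents: pd.DataFrame,
    config: CohortConfig,
    extra_log2_offset: pd.Series | None = None,
) -> pd.DataFrame:
    """Generate the well-level qPCR plate table.

    Samples are assigned to plates uniformly at random (capacity
    permitting).  CT values follow
    ``gene baseline - log2(relative template) + plate shift + well noise``;
    threshold, batch and concentration effects are injected into the
    MT_CYB sample wells only (gene-differential, since any effect common
    to both genes or shared with the same-plate REF cancels from ddCT by
    construction), with coefficients scaled so each realized variance share
    of ddCT matches ``config.variance_shares``.

    ``extra_log2_offset`` (indexed by sample id) adds to a sample's mtDNA
    log2 template — the hook used to couple, e.g., platelet levels to the
    measurement.
    """
    rng = config.rng("qpcr")
    n = len(participants)
    fixed_wells = 2 * config.ref_replicates + 2  # REF both genes + 1 NTC/gene
    capacity = config.wells_per_plate - fixed_wells
    samples_per_plate_max = capacity // (2 * config.sample_replicates)
    if samples_per_plate_max * config.n_plates < n:
        raise CohortConfigError(
            f"{n} samples exceed total plate capacity "
            f"{samples_per_plate_max * config.n_plates}")

    plate_ids = [f"P{i + 1:02d}" for i in range(config.n_plates)]
    per_batch = math.ceil(config.n_plates / config.n_batches)
    batch_of = {p: f"B{i // per_batch + 1}" for i, p in enumerate(plate_ids)}
    thresholds = {p: float(np.round(rng.uniform(0.05, 0.35), 3)) for p in plate_ids}
    plate_shift = {p: (rng.normal(0.0, config.plate_shift_sd)
                       if config.plate_shift_sd > 0 else 0.0)
                   for p in plate_ids}
    batch_effect_raw = {b: rng.normal() for b in sorted(set(batch_of.values()))}

    # uniform random assignment, then spill overfull plates
    assignment = rng.integers(0, config.n_plates, size=n)
    counts = np.bincount(assignment, minlength=config.n_plates)
    while (counts > samples_per_plate_max).any():
        over = int(np.argmax(counts))
        candidates = np.nonzero(assignment == over)[0]
        move = rng.choice(candidates)
        free = np.nonzero(counts < samples_per_plate_max)[0]
        dest = int(rng.choice(free))
        assignment[move] = dest
        counts[over] -= 1
        counts[dest] += 1

    ids = participants["id"].to_numpy()
    true_cn = latents.set_index("id")["true_cn"]
    log2cn = np.log2(true_cn.loc[ids].to_numpy())
    if extra_log2_offset is not None:
        log2cn = log2cn + extra_log2_offset.reindex(ids).fillna(0.0).to_numpy()

    # realized, empirically standardized covariates -> exact target variances
    t_raw = np.array([thresholds[plate_ids[a]] for a in assignment])
    b_raw = np.array([batch_effect_raw[batch_of[plate_ids[a]]] for a in assignment])
    c_raw = participants["dna_conc_ng_ul"].to_numpy(dtype=float)

    def _standardize(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    t_z, b_z, c_z = _standardize(t_raw), _standardize(b_raw), _standardize(c_raw)
    s_t, s_b, s_c = config.variance_shares
    resid_share = 1.0 - (s_t + s_b + s_c)
    # ddCT residual variance: signal + well-noise contribution
    noise_var = (config.well_noise_sd ** 2) * 2 * (
        1 / config.sample_replicates + 1 / config.ref_replicates)
    v0 = float(np.var(log2cn)) + noise_var
    if v0 > 0:
        beta_t = math.sqrt(s_t / resid_share * v0)
        beta_b = math.sqrt(s_b / resid_share * v0)
        beta_c = math.sqrt(s_c / resid_share * v0)
    else:
        beta_t = beta_b = beta_c = 0.0
    cyb_effect = beta_t * t_z + beta_b * b_z + beta_c * c_z

    def noise():
        return rng.normal(0.0, config.well_noise_sd) if config.well_noise_sd > 0 else 0.0

    wells = []
    labels_by_plate = {p: iter(_well_labels(config.wells_per_plate))
                       for p in plate_ids}
    for p in plate_ids:
        lab = labels_by_plate[p]
        for gene, base in (("RNASEP", config.rnasep_base_ct),
                           ("MT_CYB", config.mt_cyb_base_ct)):
            for rep in range(1, config.ref_replicates + 1):
                wells.append({
                    "plate_id": p, "batch_id": batch_of[p], "well": next(lab),
                    "role": "REF", "sample_id": "REF", "gene": gene,
                    "replicate": rep, "ct": base + plate_shift[p] + noise(),
                    "ct_threshold": thresholds[p],
                })
            contaminated = rng.random() < config.ntc_contamination_rate
            ntc_ct = (float(rng.uniform(30.0, 38.0)) if contaminated
                      else float(rng.uniform(config.ntc_min_ct, 40.0)))
            wells.append({
                "plate_id": p, "batch_id": batch_of[p], "well": next(lab),
                "role": "NTC", "sample_id": "", "gene": gene,
                "replicate": 1, "ct": ntc_ct, "ct_threshold": thresholds[p],
            })

    for i, sid in enumerate(ids):
        p = plate_ids[assignment[i]]
        lab = labels_by_plate[p]
        for gene, base in (("RNASEP", config.rnasep_base_ct),
                           ("MT_CYB", config.mt_cyb_base_ct)):
            template_log2 = log2cn[i] if gene == "MT_CYB" else 0.0
            effect = cyb_effect[i] if gene == "MT_CYB" else 0.0
            for rep in range(1, config.sample_replicates + 1):
                if rng.random() < config.amplification_failure_rate:
                    ct = float(rng.uniform(30.0, 36.0))
                else:
                    ct = (base - template_log2 - effect
                          + plate_shift[p] + noise())
                wells.append({
                    "plate_id": p, "batch_id": batch_of[p], "well": next(lab),
                    "role": "SAMPLE", "sample_id": sid, "gene": gene,
                    "replicate": rep, "ct": ct, "ct_threshold": thresholds[p],
                })
    return pd.DataFrame(wells)


# ---------------------------------------------------------------------------
# depth profiles


def simulate_depth_profiles(
    participants: pd.DataFrame,
    latents: pd.DataFrame,
    config: CohortConfig,
    subset: list[str] | None = None,
) -> dict[str, dict[str, DepthProfile]]:
    """Per-base Poisson depth over mtDNA and the autosomal reference region.

    Nuclear depth has mean ``nuclear_depth`` d; mtDNA depth has mean
    ``d * mt_depth_multiplier * true_cn``.  Returns
    ``{sample_id: {region_name: DepthProfile}}``.
    """
    rng = config.rng("depth")
    true_cn = latents.set_index("id")["true_cn"]
    ids = list(subset) if subset is not None else list(participants["id"])
    out = {}
    for sid in ids:
        nuc = rng.poisson(config.nuclear_depth, size=config.nuclear_region_length)
        mt_mean = config.nuclear_depth * config.mt_depth_multiplier * float(true_cn[sid])
        mt = rng.poisson(mt_mean, size=MT_LENGTH)
        out[sid] = {
            config.nuclear_region_name: DepthProfile(
                config.nuclear_region_name, 1, config.nuclear_region_length, nuc),
            config.mt_region_name: DepthProfile(
                config.mt_region_name, 1, MT_LENGTH, mt),
        }
    return out


# ---------------------------------------------------------------------------
# genotypes


def simulate_mtdna_genotypes(
    participants_or_n,
    config: CohortConfig,
) -> tuple[HaploidGenotypeMatrix, pd.Series]:
    """Haplogroup-structured haploid genotypes.

    The matrix contains, per haplogroup, ``defining_snps_per_haplogroup``
    SNPs carried by all of its members (hence private to it), plus the
    configured count of additional private SNPs, with the remainder of
    ``total_snps`` filled by shared polymorphic SNPs whose carriers are
    forced to span at least two haplogroups.  Counts are exact, so
    downstream private-variant detection recovers them exactly.
    """
    rng = config.rng("genotypes")
    freqs = config.haplogroup_freqs
    if not freqs:
        raise CohortConfigError("empty haplogroup frequency table")
    total_freq = sum(freqs.values())
    if not math.isclose(total_freq, 1.0, rel_tol=1e-6):
        raise CohortConfigError(f"haplogroup frequencies sum to {total_freq}")

    if isinstance(participants_or_n, int):
        ids = [f"S{i + 1:04d}" for i in range(participants_or_n)]
    else:
        ids = list(participants_or_n["id"])
    n = len(ids)
    hgs = sorted(freqs)
    if n < len(hgs):
        raise CohortConfigError("fewer individuals than haplogroups")

    # largest-remainder allocation, every haplogroup gets >= 1 member
    raw = np.array([freqs[h] * n for h in hgs])
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    rema = raw - np.floor(raw)
    while counts.sum() < n:
        j = int(np.argmax(rema))
        counts[j] += 1
        rema[j] = -1
    labels = np.repeat(hgs, counts)
    labels = rng.permutation(labels)
    members = {h: np.nonzero(labels == h)[0] for h in hgs}

    n_defining = config.defining_snps_per_haplogroup * len(hgs)
    n_private = sum(config.private_snp_counts.get(h, 0) for h in hgs)
    n_shared = config.total_snps - n_defining - n_private
    if n_shared < 0:
        raise CohortConfigError(
            f"total_snps={config.total_snps} below defining+private "
            f"({n_defining}+{n_private})")
    if len(hgs) < 2 and n_shared > 0:
        # with a single haplogroup every variant is trivially private to it;
        # shared SNPs are generated without the span-two-groups constraint
        pass
    if config.total_snps > MT_LENGTH:
        raise CohortConfigError("more SNPs than mtDNA positions")

    positions = np.sort(rng.choice(np.arange(1, MT_LENGTH + 1),
                                   size=config.total_snps, replace=False))
    calls = np.zeros((n, config.total_snps), dtype=np.int8)
    kinds = []  # (kind, haplogroup) per variant, in generation order

    col = 0
    for h in hgs:
        for _ in range(config.defining_snps_per_haplogroup):
            calls[members[h], col] = 1
            kinds.append(("defining", h))
            col += 1
    for h in hgs:
        for _ in range(config.private_snp_counts.get(h, 0)):
            carriers = rng.random(len(members[h])) < config.private_carrier_rate
            if not carriers.any():
                carriers[rng.integers(len(members[h]))] = True
            calls[members[h][carriers], col] = 1
            kinds.append(("private", h))
            col += 1
    for _ in range(n_shared):
        q = rng.uniform(0.05, 0.5)
        carriers = rng.random(n) < q
        if len(hgs) >= 2:
            carried_groups = set(labels[carriers])
            if len(carried_groups) < 2:
                pick = rng.choice(hgs, size=2, replace=False)
                for h in pick:
                    carriers[rng.choice(members[h])] = True
        elif not carriers.any():
            carriers[rng.integers(n)] = True
        calls[carriers, col] = 1
        kinds.append(("shared", ""))
        col += 1

    if config.genotype_missing_rate > 0:
        mask = rng.random(calls.shape) < config.genotype_missing_rate
        calls[mask] = -1

    # columns are kind-major (defining, private, shared); positions were
    # drawn sorted, so each column simply takes the next position
    variant_ids = [f"mt{pos}" for pos in positions]
    matrix = HaploidGenotypeMatrix(ids, variant_ids, positions, calls)
    return matrix, pd.Series(labels, index=ids, name="haplogroup")


# ---------------------------------------------------------------------------
# phenotypes


def _distribute_total(rng, total: int, n_items: int, lo: int, hi: int) -> list[int]:
    """Random composition of ``total`` into ``n_items`` integers in [lo, hi]."""
    items = []
    remaining = total
    for k in range(n_items, 0, -1):
        low = max(lo, remaining - hi * (k - 1))
        high = min(hi, remaining - lo * (k - 1))
        v = int(rng.integers(low, high + 1))
        items.append(v)
        remaining -= v
    return items


def simulate_phenotypes(
    participants: pd.DataFrame,
    latents: pd.DataFrame,
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCL-C item responses and blood-count records.

    A participant is probable-PTSD when their latent severity is positive,
    which happens with exactly the configured prevalence of their
    generation x group cell; the 17 item ratings are a random composition
    of a total drawn above or below the cutoff accordingly.  Blood counts
    are generated for a random subset (``blood_subset_size``) with the
    configured male effects in SD units.  Blood percent fractions are drawn
    independently per measure (their sum is not constrained to 100).
    """
    rng = config.rng("phenotypes")
    sev = latents.set_index("id")["ptsd_severity"]
    lo, hi = config.pclc_item_range
    max_total = hi * N_PCLC_ITEMS
    min_total = lo * N_PCLC_ITEMS
    cutoff = config.pclc_cutoff

    pclc_rows = []
    for pid in participants["id"]:
        flagged = bool(sev[pid] > 0)
        if flagged:
            total = int(rng.integers(max(cutoff, min_total), max_total + 1))
        else:
            total = int(rng.integers(min_total, max(cutoff, min_total + 1)))
        items = _distribute_total(rng, total, N_PCLC_ITEMS, lo, hi)
        row = {"participant_id": pid}
        row.update({f"item_{k + 1:02d}": v for k, v in enumerate(items)})
        pclc_rows.append(row)
    pclc = pd.DataFrame(pclc_rows)

    from .cohort_assoc import BLOOD_MEASURES
    base = {
        "WBC_x10.9_per_L": (6.5, 1.6), "RBC_x10.12_per_L": (4.7, 0.4),
        "HGB_g_per_L": (140.0, 12.0), "HCT_L_per_L": (0.42, 0.035),
        "MCV_fL": (90.0, 4.5), "PLT_x10.9_per_L": (250.0, 55.0),
        "MCH_pg": (30.0, 1.8), "MCHC_g_per_L": (335.0, 10.0),
        "RDW_percent": (13.0, 1.0), "MPV_fL": (10.5, 0.9),
        "NEU_percent": (58.0, 8.0), "LYM_percent": (30.0, 7.0),
        "MONO_percent": (8.0, 2.0), "EOS_percent": (2.5, 1.5),
        "BASO_percent": (0.6, 0.3), "NEU_x10.9_per_L": (3.8, 1.2),
        "LYM_x10.9_per_L": (2.0, 0.6), "MONO_x10.9_per_L": (0.5, 0.15),
        "EOS_x10.9_per_L": (0.17, 0.1), "BASO_x10.9_per_L": (0.04, 0.02),
    }
    n_subset = config.blood_subset_size
    if n_subset > len(participants):
        raise CohortConfigError(
            f"blood subset {n_subset} exceeds cohort size {len(participants)}")
    subset = rng.choice(participants["id"].to_numpy(), size=n_subset,
                        replace=False)
    meta = participants.set_index("id")
    blood_rows = []
    for pid in subset:
        male = float(meta.loc[pid, "sex"] == "M")
        row = {"participant_id": pid}
        for m in BLOOD_MEASURES:
            mean, sd = base[m]
            z = config.blood_sex_effects.get(m, 0.0) * male + rng.normal()
            val = mean + sd * z
            val = max(val, 0.0)
            if m.endswith("percent"):
                val = min(val, 100.0)
            row[m] = float(np.round(val, 3))
        blood_rows.append(row)
    blood = pd.DataFrame(blood_rows)
    return pclc, blood


# ---------------------------------------------------------------------------
# writers


def write_participants_csv(participants: pd.DataFrame, path) -> None:
    cols = ["id", "generation", "group", "sex", "age", "mother_id",
            "father_id", "maternal_hs_lineage", "dna_conc_ng_ul"]
    participants[cols].to_csv(path, index=False)


def write_plates_csv(wells: pd.DataFrame, path) -> None:
    cols = ["plate_id", "batch_id", "well", "role", "sample_id", "gene",
            "replicate", "ct", "ct_threshold"]
    wells[cols].to_csv(path, index=False)


def write_haplogroups_csv(labels: pd.Series, path) -> None:
    labels.rename_axis("sample_id").reset_index().to_csv(path, index=False)


def write_pclc_csv(pclc: pd.DataFrame, path) -> None:
    pclc.to_csv(path, index=False)


def write_blood_csv(blood: pd.DataFrame, path) -> None:
    blood.to_csv(path, index=False)


def read_participants_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=True)
    for col in ("mother_id", "father_id"):
        df[col] = df[col].where(df[col].notna(), None)
    return df
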