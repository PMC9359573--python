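"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generators emulate the study conditions of the RTkdr validation work:

* dual-probe CT pairs whose ΔCT concentrates at per-species three-cluster
  centers (homozygotes drop the off-allele probe late or not at all, so the
  CT-40 substitution comes into play);
* a genotyped field cohort with the published per-species genotype mix and a
  bayside/inland, land-use stratification;
* bottle-bioassay knockdown time courses that are linear in time on average;
* Sanger-style reference genotypes, including the SF-1014 class the
  dual-probe assay itself cannot distinguish from LF.

Every generator takes its seed from its spec object, and identical seeds give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables
from .assay import TemplateSeq, default_oligos, revcomp

GENOTYPES = ("LL", "LF", "FF")
CT_MAX = 40.0


# --- Noise model for the qPCR readout ----------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Distributional model of the assay readout for one species.

    ``cluster_centers`` are the FF, LF, LL ΔCT centers (strictly ascending);
    ``cluster_sd`` the within-cluster ΔCT spread in cycles; ``base_ct`` the
    CT of a matched, amplifying probe; ``dropout_prob`` the chance that the
    off-allele probe of a homozygote produces no CT at all (beyond naturally
    running past cycle 40); ``no_amp_prob`` the chance that the whole
    reaction fails.
    """

    species: str
    cluster_centers: tuple[float, float, float]
    cluster_sd: float = 1.0
    base_ct: float = 24.0
    dropout_prob: float = 0.05
    no_amp_prob: float = 0.04
    ct_max: float = CT_MAX

    def __post_init__(self):
        c = self.cluster_centers
        if not (c[0] < c[1] < c[2]):
            raise ValueError("cluster_centers must be strictly increasing (FF < LF < LL)")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be positive")
        if not (10.0 <= self.base_ct <= 35.0):
            raise ValueError("base_ct must lie in [10, 35]")
        for name in ("dropout_prob", "no_amp_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def default_noise_model(species: str) -> NoiseModel:
    """Published cluster centers with spreads chosen to match the tight
    per-genotype ΔCT distributions the assay produces (1.0 cycles for the
    widely separated Cx. pipiens clusters, 0.5 for the narrow Cx. tarsalis
    ones).

    Off-allele dropout is only plausible when that probe crosses threshold
    near the 40-cycle limit: with base CT 24 the pipiens homozygote
    off-allele probe comes up around cycle 37 and occasionally fails, while
    the tarsalis one comes up around cycle 27 and essentially never does,
    so dropout defaults to 0 there.
    """
    centers = tables.CLUSTER_CENTERS[species]
    sd = 1.0 if species == "Cx. pipiens" else 0.5
    dropout = 0.05 if species == "Cx. pipiens" else 0.0
    return NoiseModel(species=species, cluster_centers=centers, cluster_sd=sd,
                      dropout_prob=dropout)


def simulate_ct_pair(
    genotype: str, model: NoiseModel, rng: np.random.Generator
) -> tuple[float | None, float | None]:
    """Draw one specimen's (ct_tta, ct_ttt), None meaning no amplification.

    LL amplifies the TTA probe at base_ct and the TTT probe late (ΔCT near
    the LL center); FF is the mirror image; LF/SF amplify both probes
    together (the assay cannot distinguish SF from LF). Computed CTs at or
    past cycle 40 are reported as absent.
    """
    if genotype not in ("LL", "LF", "FF", "SF"):
        raise ValueError(f"unknown genotype {genotype!r}")
    if rng.random() < model.no_amp_prob:
        return None, None

    c_ff, c_lf, c_ll = model.cluster_centers
    s = model.cluster_sd / np.sqrt(2.0)
    e1, e2 = rng.normal(0.0, s, size=2)
    if genotype == "LL":
        tta = model.base_ct + e1
        ttt = None if rng.random() < model.dropout_prob else model.base_ct + c_ll + e2
    elif genotype == "FF":
        ttt = model.base_ct + e1
        tta = None if rng.random() < model.dropout_prob else model.base_ct - c_ff + e2
    else:  # LF or SF: both probes amplify together
        tta = model.base_ct + e1
        ttt = model.base_ct + c_lf + e2

    def clip(ct):
        if ct is None or ct >= model.ct_max:
            return None
        return float(max(ct, 1.0))

    return clip(tta), clip(ttt)


# --- Field cohort ------------------------------------------------------------

@dataclass(frozen=True)
class Stratum:
    species: str
    region: str
    land_use: str
    n: int
    genotype_probs: tuple[float, float, float]  # LL, LF, FF

    def __post_init__(self):
        if self.region not in ("bayside", "inland"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.land_use not in ("wildlife", "urban", "industrial", "agriculture"):
            raise ValueError(f"unknown land use {self.land_use!r}")
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        p = self.genotype_probs
        if any(not (0.0 <= q <= 1.0) for q in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(f"genotype_probs {p} must be in [0,1] and sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    strata: tuple[Stratum, ...]
    sf_prob: float = 0.0  # fraction of LF draws that are truly SF-1014
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.sf_prob <= 1.0):
            raise ValueError("sf_prob must be in [0, 1]")


def default_cohort_spec(seed: int = 0, sf_prob: float = 0.0) -> CohortSpec:
    """The published survey emulated: per-species genotype mixes and totals
    from the genotype count table, split across region and land use by a
    fixed scheme that reproduces the printed species and region totals (the
    true specimen-level cross-classification was never published, so the
    cross-cells are synthetic)."""
    species_counts = tables.SPECIES_COUNTS

    def probs(sp):
        ll, lf, ff = species_counts[sp]
        n = ll + lf + ff
        return (ll / n, lf / n, ff / n)

    # region split: all 126 Cx. erythrothorax bayside; pipiens/tarsalis split
    # so that bayside totals 744 and inland 633 as printed
    layout = [
        ("Cx. erythrothorax", "bayside", 126),
        ("Cx. pipiens", "bayside", 300),
        ("Cx. pipiens", "inland", 444),
        ("Cx. tarsalis", "bayside", 318),
        ("Cx. tarsalis", "inland", 189),
    ]
    landuse_split = {
        "bayside": (("wildlife", 0.6), ("urban", 0.4)),
        "inland": (("industrial", 0.6), ("agriculture", 0.4)),
    }
    strata = []
    for sp, region, n in layout:
        if sp == "Cx. erythrothorax":
            strata.append(Stratum(sp, region, "wildlife", n, probs(sp)))
            continue
        (lu1, w1), (lu2, _) = landuse_split[region]
        n1 = round(n * w1)
        strata.append(Stratum(sp, region, lu1, n1, probs(sp)))
        strata.append(Stratum(sp, region, lu2, n - n1, probs(sp)))
    return CohortSpec(strata=tuple(strata), sf_prob=sf_prob, seed=seed)


def simulate_specimens(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort: one row per specimen with stratum labels and the true
    genotype. A fraction ``sf_prob`` of LF draws is relabelled SF-1014 (which
    the dual-probe assay will still read as LF)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    counter = 0
    for st in spec.strata:
        draws = rng.choice(3, size=st.n, p=st.genotype_probs)
        for d in draws:
            geno = GENOTYPES[d]
            if geno == "LF" and spec.sf_prob > 0 and rng.random() < spec.sf_prob:
                geno = "SF"
            counter += 1
            rows.append(
                {
                    "specimen_id": f"S{counter:05d}",
                    "species": st.species,
                    "region": st.region,
                    "land_use": st.land_use,
                    "true_genotype": geno,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["specimen_id", "species", "region", "land_use", "true_genotype"],
    )


def simulate_plate(
    specimens: pd.DataFrame,
    models: dict[str, NoiseModel] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the noise model over a simulated cohort: returns plate rows
    (specimen_id, species, well, ct_tta/ct_fam, ct_ttt/ct_hex)."""
    rng = np.random.default_rng(seed)
    if models is None:
        models = {sp: default_noise_model(sp) for sp in tables.CLUSTER_CENTERS}
    rows = []
    for i, rec in enumerate(specimens.itertuples(index=False)):
        model = models.get(rec.species)
        if model is None:
            # species without published centers: reuse the tarsalis-scale model
            model = default_noise_model("Cx. tarsalis")
        tta, ttt = simulate_ct_pair(rec.true_genotype, model, rng)
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "species": rec.species,
                "well": f"{chr(65 + (i // 12) % 8)}{i % 12 + 1}",
                "ct_fam": tta,
                "ct_hex": ttt,
            }
        )
    return pd.DataFrame(rows, columns=["specimen_id", "species", "well", "ct_fam", "ct_hex"])


def simulate_reference_calls(
    truth, assay_error_rate: float = 0.0, seed: int = 0
) -> list[str]:
    """Sanger-style reference genotypes: equal to truth except for an
    ``assay_error_rate`` fraction perturbed to a uniformly chosen different
    genotype. The reference sees SF-1014 as SF (sequencing resolves it); only
    the dual-probe assay collapses SF onto LF."""
    if not (0.0 <= assay_error_rate <= 1.0):
        raise ValueError("error rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    universe = ("LL", "LF", "FF", "SF")
    for g in truth:
        if assay_error_rate > 0 and rng.random() < assay_error_rate:
            alternatives = [x for x in universe if x != g]
            out.append(alternatives[rng.integers(len(alternatives))])
        else:
            out.append(g)
    return out


# --- Bottle bioassay ----------------------------------------------------------

@dataclass(frozen=True)
class BioassaySpec:
    """Knockdown time-course generator: expected cumulative knockdown percent
    at time t equals clamp(slope*t + intercept, 0, 100)."""

    strain: str
    insecticide: str
    slope: float       # percent per minute
    intercept: float   # percent
    n_bottles: int = 3
    n_per_bottle: int = 22
    t_max: int = 120
    t_step: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_bottles <= 0:
            raise ValueError("n_bottles must be positive")
        if not (21 <= self.n_per_bottle <= 23):
            raise ValueError("n_per_bottle must be 21-23")
        if self.t_max % self.t_step != 0:
            raise ValueError("time grid must be evenly spaced")

    @property
    def time_grid(self) -> tuple[int, ...]:
        return tuple(range(self.t_step, self.t_max + 1, self.t_step))


def default_bioassay_spec(strain: str, insecticide: str, seed: int = 0) -> BioassaySpec:
    slope, intercept, _ = tables.BIOASSAY_LINES[(strain, insecticide)]
    return BioassaySpec(strain=strain, insecticide=insecticide,
                        slope=slope, intercept=intercept, seed=seed)


def simulate_bioassay(spec: BioassaySpec) -> pd.DataFrame:
    """Draw each mosquito's knockdown time by inverting the clamped linear
    cumulative-knockdown curve, then bin to the observation grid. Returns one
    row per bottle x timepoint with nondecreasing cumulative counts."""
    rng = np.random.default_rng(spec.seed)
    grid = np.array(spec.time_grid, dtype=float)
    rows = []
    for b in range(1, spec.n_bottles + 1):
        u = rng.random(spec.n_per_bottle)
        if spec.slope > 0:
            t_kd = (100.0 * u - spec.intercept) / spec.slope
            t_kd = np.clip(t_kd, 0.0, None)
        else:
            # flat curve: knocked down immediately iff intercept already covers u
            t_kd = np.where(100.0 * u <= spec.intercept, 0.0, np.inf)
        for t in grid:
            rows.append(
                {
                    "strain": spec.strain,
                    "insecticide": spec.insecticide,
                    "bottle": b,
                    "time_min": int(t),
                    "n_total": spec.n_per_bottle,
                    "n_knocked": int(np.sum(t_kd <= t)),
                }
            )
    return pd.DataFrame(rows)


# --- Synthetic Vgsc templates -------------------------------------------------

def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def synthetic_vgsc_templates(codon: str = "TTA", seed: int = 20) -> dict[str, TemplateSeq]:
    """Synthetic stand-ins for the Vgsc cDNA templates the assay was designed
    against (the deposited accessions are not redistributed here). Each
    template embeds the real oligo binding sites with the published geometry:

    * ``tarsalis_syn``  — reference-like template; the sequencing primer and
      the reverse primer delimit a 373-bp product containing the probe site
      and the 1014 codon (``codon``, TTA by default).
    * ``erythrothorax_syn`` — identical across the product region (the two
      sister species are 100% identical over the amplicon), different flanks.
    * ``pipiens_syn``   — perfect primer sites but two mismatches under the
      probe and ~4% divergence elsewhere in the product, mimicking the more
      distant species the assay still amplifies.
    """
    rng = np.random.default_rng(seed)
    oligos = default_oligos()
    fwd_seq = oligos["RTSeq_Fwd"].bases
    kdr_fwd = oligos["RTkdr_Fwd"].bases
    rev_site = revcomp(oligos["RTkdr_Rev"].bases)
    probe_sense = revcomp(oligos["RTkdr_TTA"].bases)  # coding strand, codon inside

    idx = probe_sense.find("TTA")
    sense_ttt = revcomp(oligos["RTkdr_TTT"].bases)
    while sense_ttt[idx : idx + 3] != "TTT":
        idx = probe_sense.find("TTA", idx + 1)
    probe_ctx = probe_sense[:idx] + codon + probe_sense[idx + 3 :]

    product_len = tables.SEQ_PRODUCT_LENGTH
    fill_b, fill_c = 40, 60
    fill_a = product_len - len(fwd_seq) - len(kdr_fwd) - fill_b - len(probe_ctx) - fill_c - len(rev_site)
    parts = [
        fwd_seq, _filler(rng, fill_a), kdr_fwd, _filler(rng, fill_b),
        probe_ctx, _filler(rng, fill_c), rev_site,
    ]
    product = "".join(parts)
    assert len(product) == product_len

    flank5, flank3 = _filler(rng, 60), _filler(rng, 60)
    tarsalis = flank5 + product + flank3
    ery_f5, ery_f3 = _filler(rng, 45), _filler(rng, 75)
    erythro = ery_f5 + product + ery_f3

    # pipiens-like: mutate 2 bases under the probe (away from the codon) and
    # ~4% of filler positions; primer footprints stay exact
    prod = list(product)
    probe_start = len(fwd_seq) + fill_a + len(kdr_fwd) + fill_b
    codon_start = probe_start + idx

    def transversion(b):
        return {"A": "C", "C": "A", "G": "T", "T": "G"}[b]

    for off in (4, 24):  # inside the probe window, outside the codon
        pos = probe_start + off
        assert not (codon_start <= pos < codon_start + 3)
        prod[pos] = transversion(prod[pos])
    protected = set(range(0, len(fwd_seq)))
    protected |= set(range(len(fwd_seq) + fill_a, len(fwd_seq) + fill_a + len(kdr_fwd)))
    protected |= set(range(probe_start, probe_start + len(probe_ctx)))
    protected |= set(range(product_len - len(rev_site), product_len))
    candidates = [i for i in range(product_len) if i not in protected]
    for pos in rng.choice(candidates, size=12, replace=False):
        prod[pos] = transversion(prod[pos])
    pipiens = _filler(rng, 55) + "".join(prod) + _filler(rng, 65)

    return {
        "tarsalis_syn": TemplateSeq("tarsalis_syn", tarsalis,
                                    "synthetic Cx. tarsalis-like Vgsc cDNA fragment"),
        "erythrothorax_syn": TemplateSeq("erythrothorax_syn", erythro,
                                         "synthetic Cx. erythrothorax-like Vgsc cDNA fragment"),
        "pipiens_syn": TemplateSeq("pipiens_syn", pipiens,
                                   "synthetic Cx. pipiens-like Vgsc cDNA fragment"),
    }
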