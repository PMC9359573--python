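"""Published reference values for the Culex RTkdr assay and the Alameda County survey.

Everything here is a printed number from the assay's validation study: the
oligonucleotide set, per-species ΔCT cluster centers and decision bands, the
bottle-bioassay knockdown regression lines, and the stratified genotype count
tables that feed the allele-frequency and ordinal-regression analyses. These
constants are *inputs* to the statistics modules, never outputs.
"""

from __future__ import annotations

# --- Assay oligonucleotides -------------------------------------------------
# Probe strings carry their chemistry annotations (reporter dye, internal and
# 3' quenchers) exactly as ordered; parsing strips them to pure bases.
OLIGOS = [
    # (name, role, sequence as ordered, reporter)
    ("RTSeq_Fwd", "forward", "ATCTGACGTTTGTGCTCTGC", None),
    ("RTkdr_Fwd", "forward", "CCTGCATTCCGTTCTTCTTG", None),
    ("RTkdr_Rev", "reverse", "GCGATCTTGTTCGTTTCGTT", None),
    ("RTkdr_TTA", "probe", "FAM-GGTTAAGTA/ZEN/CGACTAAGTTTCCTATCACTAC-3IABkFQ", "FAM"),
    ("RTkdr_TTT", "probe", "HEX-GGTTAAGTA/ZEN/CGACAAAGTTTCCTATCACTAC-3IABkFQ", "HEX"),
]

#: Length of the Sanger-sequencing RT-PCR product (RTSeq_Fwd .. RTkdr_Rev).
SEQ_PRODUCT_LENGTH = 373

# --- ΔCT interpretation, per species ---------------------------------------
# Final k-means cluster centers (FF, LF, LL order = ascending ΔCT).
CLUSTER_CENTERS = {
    "Cx. pipiens": (-13.212, -0.871, 12.691),
    "Cx. tarsalis": (-2.944, -0.089, 3.107),
}

# ΔCT decision bands as printed: > ll_min is LL, < ff_max is FF,
# lf_low..lf_high inclusive is LF; values falling in the gaps the printed
# bands leave are UNDETERMINED (the study reviewed such curves manually).
THRESHOLD_BANDS = {
    "Cx. pipiens": {"ff_max": -4.0, "lf_low": -2.0, "lf_high": 4.9, "ll_min": 5.0},
    "Cx. tarsalis": {"ff_max": -2.0, "lf_low": -1.0, "lf_high": 1.0, "ll_min": 2.0},
}

#: Per-species ΔCT sample sizes behind the published cluster centers.
CLUSTER_N = {"Cx. pipiens": 264, "Cx. tarsalis": 360}

#: One-way ANOVA of ΔCT by assigned genotype, as published.
ANOVA_F = {"Cx. pipiens": (23644.6, 2, 261), "Cx. tarsalis": (1228.5, 2, 357)}

# --- Bottle bioassay ---------------------------------------------------------
# Knockdown-percent-vs-time regression lines (slope %/min, intercept %, R^2)
# for the susceptible KNWR and resistant Conaway Cx. tarsalis strains.
BIOASSAY_LINES = {
    ("KNWR", "deltamethrin"): (1.785, -6.627, 0.7403),
    ("Conaway", "deltamethrin"): (0.1977, -4.588, 0.3585),
    ("KNWR", "permethrin"): (1.818, -1.553, 0.9283),
    ("Conaway", "permethrin"): (0.0870, -2.156, 0.3584),
}

# Conaway-strain genotype x knockdown outcome from the single sequenced bottle
# per insecticide. Columns LL, LF, FF, SF; rows: not knocked down / knocked down
# at 120 min. SF is visible to Sanger sequencing only.
BIOASSAY_GENOTYPES = {
    "permethrin": {"not_knocked": (0, 0, 11, 0), "knocked": (1, 2, 9, 3)},
    "deltamethrin": {"not_knocked": (0, 0, 12, 0), "knocked": (0, 4, 8, 3)},
}

GENOTYPE_COLUMNS = ("LL", "LF", "FF", "SF")

# --- Assay validation counts -------------------------------------------------
# RTkdr vs the gDNA-based qPCR assay on field Cx. pipiens: 75 tested, 3
# excluded for no amplification by cycle 30, 69 of 72 concordant.
QPCR_COMPARISON = {"n_tested": 75, "n_excluded": 3, "n_valid": 72, "n_concordant": 69}

# RTkdr vs Sanger sequencing across five field species plus two lab strains:
# 190 specimens, one discordant (assay FF, chromatogram LF).
SANGER_COMPARISON = {"n_valid": 190, "n_concordant": 189}

# --- Survey genotype counts (species / region / land-use marginals) ----------
# Rows: stratum -> (n_LL, n_LF, n_FF).
SPECIES_COUNTS = {
    "Cx. erythrothorax": (126, 0, 0),
    "Cx. tarsalis": (401, 57, 49),
    "Cx. pipiens": (208, 226, 310),
}

REGION_COUNTS = {
    "bayside": (519, 136, 89),
    "inland": (216, 147, 270),
}

LAND_USE_COUNTS = {
    "wildlife": (296, 94, 94),
    "urban": (123, 80, 100),
    "industrial": (251, 83, 115),
    "agriculture": (65, 26, 50),
}

# All 126 Cx. erythrothorax were bayside, wildlife, homozygous LL; the ordinal
# models are restricted to Cx. pipiens and Cx. tarsalis, so single-covariate
# region and land-use fits subtract them from the corresponding marginal rows.
ERYTHROTHORAX_STRATUM = {"region": "bayside", "land_use": "wildlife", "n_ll": 126}


def region_counts_model_population() -> dict[str, tuple[int, int, int]]:
    """Region marginals restricted to the two modelled species."""
    out = dict(REGION_COUNTS)
    ll, lf, ff = out["bayside"]
    out["bayside"] = (ll - ERYTHROTHORAX_STRATUM["n_ll"], lf, ff)
    return out


def land_use_counts_model_population() -> dict[str, tuple[int, int, int]]:
    """Land-use marginals restricted to the two modelled species."""
    out = dict(LAND_USE_COUNTS)
    ll, lf, ff = out["wildlife"]
    out["wildlife"] = (ll - ERYTHROTHORAX_STRATUM["n_ll"], lf, ff)
    return out
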