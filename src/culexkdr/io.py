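"""CSV/FASTA/JSON formats, trap-site geography, and the end-to-end pipeline.

File dialects
-------------
plate CSV     : specimen_id, species, well, ct_fam, ct_hex  (empty CT = no
                amplification; the FAM probe reports the wild-type TTA allele,
                HEX the mutant TTT allele)
metadata CSV  : specimen_id, site_id, latitude, longitude, region, land_use
bioassay CSV  : strain, insecticide, bottle, time_min, n_total, n_knocked
calls CSV     : specimen_id, species, delta_ct, genotype, method, flags

Trap sites within a merge radius (1 km by default) are combined by
single-linkage connected components over great-circle distances.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import calling, stats, tables
from .assay import TemplateSeq
from .calling import GenotypeCall, WellReading

logger = logging.getLogger("culexkdr")

SCHEMA_VERSION = "1.0"
EARTH_RADIUS_KM = 6371.0088

REGIONS = ("bayside", "inland")
LAND_USES = ("wildlife", "urban", "industrial", "agriculture")


class FormatError(ValueError):
    """Malformed input file; the message carries the offending line number."""


# --- Plate CSV ---------------------------------------------------------------

PLATE_COLUMNS = ["specimen_id", "species", "well", "ct_fam", "ct_hex"]


def _parse_ct(raw: str, line_no: int, col: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise FormatError(f"line {line_no}: non-numeric {col} value {raw!r}") from None


def read_plate_csv(path) -> list[WellReading]:
    path = Path(path)
    readings: list[WellReading] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in PLATE_COLUMNS[:2] + PLATE_COLUMNS[3:] if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path.name}: missing required column(s) {missing}")
        for line_no, row in enumerate(reader, start=2):
            sid = row["specimen_id"].strip()
            if not sid:
                raise FormatError(f"line {line_no}: empty specimen_id")
            if sid in seen:
                raise FormatError(f"line {line_no}: duplicate specimen id {sid!r}")
            seen.add(sid)
            readings.append(
                WellReading(
                    specimen_id=sid,
                    species=row["species"].strip(),
                    ct_tta=_parse_ct(row["ct_fam"], line_no, "ct_fam"),
                    ct_ttt=_parse_ct(row["ct_hex"], line_no, "ct_hex"),
                )
            )
    logger.info("read %d plate records from %s", len(readings), path)
    return readings


def write_plate_csv(path, readings: list[WellReading] | pd.DataFrame) -> None:
    path = Path(path)
    if isinstance(readings, pd.DataFrame):
        df = readings.copy()
    else:
        df = pd.DataFrame(
            {
                "specimen_id": [r.specimen_id for r in readings],
                "species": [r.species for r in readings],
                "well": ["" for _ in readings],
                "ct_fam": [r.ct_tta for r in readings],
                "ct_hex": [r.ct_ttt for r in readings],
            }
        )
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL, float_format="%.12g")


# --- Metadata CSV ------------------------------------------------------------

@dataclass(frozen=True)
class TrapSite:
    site_id: str
    latitude: float
    longitude: float
    region: str
    land_use: str

    def __post_init__(self):
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError(f"site {self.site_id!r}: invalid coordinates")
        if self.region not in REGIONS:
            raise ValueError(f"site {self.site_id!r}: unknown region {self.region!r}")
        if self.land_use not in LAND_USES:
            raise ValueError(f"site {self.site_id!r}: unknown land use {self.land_use!r}")


def read_metadata_csv(path) -> tuple[dict[str, TrapSite], dict[str, str]]:
    """Returns (sites by id, specimen_id -> site_id)."""
    path = Path(path)
    sites: dict[str, TrapSite] = {}
    specimen_site: dict[str, str] = {}
    required = ["specimen_id", "site_id", "latitude", "longitude", "region", "land_use"]
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path.name}: missing required column(s) {missing}")
        for line_no, row in enumerate(reader, start=2):
            sid = row["specimen_id"].strip()
            if sid in specimen_site:
                raise FormatError(f"line {line_no}: duplicate specimen id {sid!r}")
            try:
                site = TrapSite(
                    site_id=row["site_id"].strip(),
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    region=row["region"].strip(),
                    land_use=row["land_use"].strip(),
                )
            except ValueError as exc:
                raise FormatError(f"line {line_no}: {exc}") from None
            existing = sites.get(site.site_id)
            if existing is not None and existing != site:
                raise FormatError(
                    f"line {line_no}: site {site.site_id!r} redefined inconsistently"
                )
            sites[site.site_id] = site
            specimen_site[sid] = site.site_id
    return sites, specimen_site


# --- Calls CSV and report JSON ----------------------------------------------

def write_calls_csv(path, calls: list[GenotypeCall], species: dict[str, str] | None = None) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        w.writerow(["specimen_id", "species", "delta_ct", "genotype", "method", "flags"])
        for c in calls:
            w.writerow(
                [
                    c.specimen_id,
                    (species or {}).get(c.specimen_id, ""),
                    "" if math.isnan(c.delta_ct) else f"{c.delta_ct:.12g}",
                    c.genotype,
                    c.method,
                    ";".join(sorted(c.flags)),
                ]
            )


def read_calls_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"specimen_id": str, "genotype": str})
    missing = {"specimen_id", "genotype"} - set(df.columns)
    if missing:
        raise FormatError(f"calls file missing column(s) {sorted(missing)}")
    return df


def write_report_json(path, report: dict) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **report}
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# --- FASTA -------------------------------------------------------------------

def read_fasta(path) -> list[TemplateSeq]:
    return [
        TemplateSeq(id=rec.id, bases=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, templates: list[TemplateSeq]) -> None:
    records = [
        SeqRecord(Seq(t.bases), id=t.id, description=t.description) for t in templates
    ]
    SeqIO.write(records, str(path), "fasta")


# --- Geography ---------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on a spherical Earth (radius 6371.0088 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def merge_sites(sites: list[TrapSite], radius_km: float = 1.0) -> dict[str, str]:
    """Single-linkage merge: connected components of the graph joining sites
    at haversine distance <= radius_km. Cluster id = lexicographically
    smallest member site id. Invariant to input order and id relabelling."""
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    ordered = sorted(sites, key=lambda s: s.site_id)
    n = len(ordered)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(
                ordered[i].latitude, ordered[i].longitude,
                ordered[j].latitude, ordered[j].longitude,
            )
            if d <= radius_km:
                union(i, j)

    out = {}
    for i, s in enumerate(ordered):
        out[s.site_id] = ordered[find(i)].site_id
    return out


# --- Pipeline ----------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run configuration. ``plate`` and ``metadata`` may be paths
    to CSVs or None, in which case a synthetic cohort at the published survey
    conditions is generated from ``seed``."""

    out_dir: Path
    plate: Path | None = None
    metadata: Path | None = None
    seed: int = 0
    method: str = "cluster"          # cluster | threshold
    qc_cutoff_cycle: float = 30.0
    ct_max: float = calling.CT_MAX
    merge_radius_km: float = 1.0
    cluster_restarts: int = 8

    def __post_init__(self):
        if self.merge_radius_km <= 0:
            raise ValueError("merge radius must be positive")
        if not (0 < self.qc_cutoff_cycle <= 40):
            raise ValueError("QC cutoff must lie in (0, 40]")
        if self.method not in ("cluster", "threshold", "both"):
            raise ValueError(f"unknown calling method {self.method!r}")
        self.out_dir = Path(self.out_dir)


def call_plate(
    readings: list[WellReading],
    method: str = "cluster",
    qc_cutoff_cycle: float = 30.0,
    ct_max: float = calling.CT_MAX,
    seed: int = 0,
    restarts: int = 8,
    min_cluster_gap: float = 1.5,
) -> tuple[list[GenotypeCall], dict]:
    """QC-filter, compute ΔCT, and call genotypes per species.

    Three-cluster calling assumes all three genotypes are present; when the
    fitted centers are closer than ``min_cluster_gap`` cycles the species'
    ΔCT distribution does not actually have three modes (e.g. a monomorphic
    population) and the calls fall back to decision bands — the species' own
    if published, otherwise the narrow Cx. tarsalis scale, which is how the
    monomorphic sister species was read in the validation study.

    Returns the calls (EXCLUDED rows included, carrying their QC flags) and a
    per-species summary with cluster centers / ANOVA where applicable.
    """
    kept, excluded = calling.qc_filter(readings, qc_cutoff_cycle)
    calls: list[GenotypeCall] = []
    for r in excluded:
        _, flags = calling.compute_delta_ct(r, ct_max)
        calls.append(
            GenotypeCall(
                specimen_id=r.specimen_id, delta_ct=float("nan"),
                genotype="EXCLUDED", method=method,
                flags=flags | {calling.FLAG_NO_AMP},
            )
        )
    summary: dict = {
        "n_input": len(readings),
        "n_excluded": len(excluded),
        "exclusion_fraction": len(excluded) / len(readings) if readings else 0.0,
        "species": {},
    }

    by_species: dict[str, list[tuple[str, float, frozenset]]] = {}
    for r in kept:
        d, flags = calling.compute_delta_ct(r, ct_max)
        by_species.setdefault(r.species, []).append((r.specimen_id, d, flags))

    for sp, rows in sorted(by_species.items()):
        ids = [x[0] for x in rows]
        deltas = np.array([x[1] for x in rows])
        base_flags = {x[0]: x[2] for x in rows}
        sp_summary: dict = {"n": len(rows)}
        use = method
        if method == "threshold" and calling.species_bands(sp) is None:
            logger.warning("no published bands for %s; falling back to clustering", sp)
            use = "cluster"
        if use in ("cluster", "both"):
            try:
                model = calling.kmeans_1d(deltas, k=3, seed=seed, restarts=restarts)
            except ValueError:
                logger.warning("too few distinct ΔCT values for %s; using bands", sp)
                use, model = "threshold", None
            if model is not None and np.min(np.diff(model.centers)) < min_cluster_gap:
                logger.warning(
                    "%s ΔCT values do not separate into three clusters "
                    "(min center gap %.2f cycles); using decision bands",
                    sp, float(np.min(np.diff(model.centers))),
                )
                sp_summary["cluster_degenerate"] = True
                use = "threshold"
            elif model is not None:
                sp_calls = calling.calls_from_clusters(model, deltas, ids)
                sp_summary["cluster_centers"] = model.centers.tolist()
                sp_summary["kmeans_iterations"] = model.iterations
                f, dfb, dfw, pv = calling.anova_delta_by_genotype(
                    deltas, [c.genotype for c in sp_calls]
                )
                sp_summary["anova"] = {"F": f, "df": [dfb, dfw], "p": pv}
        if use == "threshold":
            bands = calling.species_bands(sp) or calling.species_bands("Cx. tarsalis")
            sp_calls = calling.calls_from_thresholds(deltas, bands, ids)
            sp_summary["bands_species"] = bands.species
        for c in sp_calls:
            c.flags = frozenset(c.flags | base_flags[c.specimen_id])
        calls.extend(sp_calls)
        summary["species"][sp] = sp_summary

    logger.info(
        "called %d specimens (%d excluded)", len(calls), summary["n_excluded"]
    )
    return calls, summary


def genotype_count_table(calls_df: pd.DataFrame, by: str) -> dict[str, tuple[int, int, int]]:
    """Stratified (n_LL, n_LF, n_FF) counts from a calls+metadata frame,
    ignoring UNDETERMINED/EXCLUDED rows."""
    usable = calls_df[calls_df["genotype"].isin(stats.GENOTYPE_ORDER)]
    out = {}
    for key, grp in usable.groupby(by, observed=True):
        vc = grp["genotype"].value_counts()
        out[str(key)] = tuple(int(vc.get(g, 0)) for g in stats.GENOTYPE_ORDER)
    return out


def pipeline_run(config: RunConfig) -> dict:
    """simulate/read -> QC -> ΔCT -> genotype calls -> stratified counts ->
    allele frequencies (species, region, land use, merged trap sites) ->
    ordinal-regression report. Deterministic given the seed."""
    from . import synthetic

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    if config.plate is None:
        spec = synthetic.default_cohort_spec(seed=config.seed)
        specimens = synthetic.simulate_specimens(spec)
        plate_df = synthetic.simulate_plate(specimens, seed=config.seed + 1)
        readings = [
            WellReading(
                specimen_id=r.specimen_id, species=r.species,
                ct_tta=None if pd.isna(r.ct_fam) else float(r.ct_fam),
                ct_ttt=None if pd.isna(r.ct_hex) else float(r.ct_hex),
            )
            for r in plate_df.itertuples(index=False)
        ]
        meta = specimens.set_index("specimen_id")[["region", "land_use"]]
        sites, specimen_site = {}, {}
    else:
        readings = read_plate_csv(config.plate)
        if not readings:
            raise FormatError(f"empty plate file {config.plate}")
        sites, specimen_site = (
            read_metadata_csv(config.metadata) if config.metadata else ({}, {})
        )
        meta_rows = {
            sid: {
                "region": sites[site].region,
                "land_use": sites[site].land_use,
            }
            for sid, site in specimen_site.items()
        }
        meta = pd.DataFrame.from_dict(meta_rows, orient="index")

    calls, summary = call_plate(
        readings,
        method=config.method if config.method != "both" else "cluster",
        qc_cutoff_cycle=config.qc_cutoff_cycle,
        ct_max=config.ct_max,
        seed=config.seed,
    )
    species_map = {r.specimen_id: r.species for r in readings}
    write_calls_csv(out / "calls.csv", calls, species_map)

    calls_df = pd.DataFrame(
        {
            "specimen_id": [c.specimen_id for c in calls],
            "genotype": [c.genotype for c in calls],
            "species": [species_map.get(c.specimen_id, "") for c in calls],
        }
    )
    if not meta.empty:
        calls_df = calls_df.join(meta, on="specimen_id")

    report: dict = {"seed": config.seed, "calling": summary, "allele_frequency": {}}
    count_tables: dict[str, dict] = {}
    for stratum in ("species", "region", "land_use"):
        if stratum not in calls_df.columns:
            continue
        rows = genotype_count_table(calls_df, stratum)
        count_tables[stratum] = rows
        report["allele_frequency"][stratum] = {
            k: {
                "f": stats.allele_frequency(*v).f,
                "se": stats.allele_frequency(*v).se,
                "n": sum(v),
            }
            for k, v in rows.items()
        }

    pd.DataFrame(
        [
            {"stratum": strat, "level": lvl, "n_LL": v[0], "n_LF": v[1], "n_FF": v[2]}
            for strat, rows in count_tables.items()
            for lvl, v in rows.items()
        ]
    ).to_csv(out / "genotype_counts.csv", index=False)

    # per merged-trap-site-cluster allele frequencies
    if sites and specimen_site:
        cluster_of = merge_sites(list(sites.values()), config.merge_radius_km)
        calls_df["site_cluster"] = calls_df["specimen_id"].map(
            lambda s: cluster_of.get(specimen_site.get(s, ""), "")
        )
        rows = genotype_count_table(calls_df[calls_df["site_cluster"] != ""], "site_cluster")
        report["allele_frequency"]["site_cluster"] = {
            k: {"f": stats.allele_frequency(*v).f, "n": sum(v)} for k, v in rows.items()
        }

    # ordinal model: species effect, modelled species only
    sp_rows = count_tables.get("species", {})
    model_rows = {
        k: v for k, v in sp_rows.items() if k in ("Cx. tarsalis", "Cx. pipiens") and sum(v) > 0
    }
    if len(model_rows) == 2 and all(sum(v[1:]) > 0 for v in model_rows.values()):
        fit = stats.fit_proportional_odds_counts(model_rows, reference="Cx. tarsalis")
        report["ordinal_species"] = {
            "odds_ratios": fit.odds_ratios,
            "ci": {k: [fit.ci_low[k], fit.ci_high[k]] for k in fit.odds_ratios},
            "p_values": fit.p_values,
            "converged": fit.converged,
        }

    write_report_json(out / "report.json", report)
    return report
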