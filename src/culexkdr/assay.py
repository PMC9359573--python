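"""In-silico evaluation of the Culex RTkdr oligos against Vgsc cDNA templates.

The assay genotypes the kdr L1014F locus from cDNA: two primers flank the 1014
codon and two competing TaqMan probes (antisense to the coding strand) report
the wild-type TTA (Leu) and mutant TTT (Phe) alleles. This module locates
primer/probe binding sites on a template, extracts the PCR product, counts
probe mismatches, measures cross-species amplicon identity, and reads the
1014 genotype directly off a sequenced amplicon.

Coordinates are 0-based half-open internally; report helpers convert to
1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

__all__ = [
    "Oligo",
    "TemplateSeq",
    "AmpliconResult",
    "PcrOutcome",
    "parse_oligo",
    "default_oligos",
    "find_binding_site",
    "in_silico_pcr",
    "probe_mismatch_count",
    "percent_identity",
    "genotype_from_sequence",
]

_ANNOTATION = re.compile(
    r"^(FAM-|HEX-|VIC-|CY5-)|(/ZEN/)|(-3IABkFQ$)|(-BHQ\d$)|(-MGB$)", re.IGNORECASE
)
_VALID_OLIGO = re.compile(r"^[ACGT]+$")
_VALID_TEMPLATE = re.compile(r"^[ACGTN]+$")


def _strip_annotations(seq: str) -> str:
    s = seq.strip().upper()
    prev = None
    while prev != s:
        prev = s
        s = _ANNOTATION.sub("", s)
    return s


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Oligo:
    """A primer or probe, reduced to pure bases (chemistry stripped)."""

    name: str
    bases: str
    role: str  # forward | reverse | probe
    reporter: str | None = None

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"oligo {self.name!r}: empty sequence")
        if not _VALID_OLIGO.match(self.bases):
            raise ValueError(f"oligo {self.name!r}: non-ACGT bases in {self.bases!r}")
        if self.role not in ("forward", "reverse", "probe"):
            raise ValueError(f"oligo {self.name!r}: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.bases)


def parse_oligo(name: str, role: str, sequence: str, reporter: str | None = None) -> Oligo:
    """Build an Oligo from an ordered sequence string, stripping reporter/quencher
    annotations (FAM-/HEX- prefixes, /ZEN/ internal quencher, -3IABkFQ)."""
    return Oligo(name=name, bases=_strip_annotations(sequence), role=role, reporter=reporter)


def default_oligos() -> dict[str, Oligo]:
    """The published RTkdr primer/probe set, parsed."""
    from . import tables

    return {
        name: parse_oligo(name, role, seq, rep)
        for name, role, seq, rep in tables.OLIGOS
    }


@dataclass(frozen=True)
class TemplateSeq:
    id: str
    bases: str
    description: str = ""

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"template {self.id!r}: empty sequence")
        if not _VALID_TEMPLATE.match(self.bases.upper()):
            raise ValueError(f"template {self.id!r}: non-ACGTN bases")
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AmpliconResult:
    template_id: str
    start: int  # 0-based, includes the forward-primer footprint
    end: int    # half-open, includes the reverse-primer footprint
    bases: str
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def report_coords(self) -> tuple[int, int]:
        """1-based inclusive coordinates for human-readable output."""
        return self.start + 1, self.end


@dataclass
class PcrOutcome:
    """Result of an in-silico PCR: ``status`` is one of ``ok``,
    ``no_amplification``, ``fwd_only``, ``rev_only``. On ``ok`` the shortest
    valid product is in ``amplicon`` and every valid product in ``products``."""

    status: str
    amplicon: AmpliconResult | None = None
    products: list[AmpliconResult] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_binding_site(
    template: TemplateSeq | str,
    oligo: Oligo | str,
    max_mismatch: int = 0,
) -> list[tuple[int, str, int]]:
    """Scan both strands of ``template`` for windows within ``max_mismatch``
    Hamming distance of the oligo.

    A minus-strand hit at plus-strand window ``[start, start+len)`` means the
    oligo matches the reverse complement of that window. ``N`` template bases
    count as mismatches. Hits are sorted by (mismatches, start, strand).
    """
    tmpl = template.bases if isinstance(template, TemplateSeq) else template.upper()
    obases = oligo.bases if isinstance(oligo, Oligo) else oligo.upper()
    if not tmpl or not obases:
        raise ValueError("empty template or oligo")
    n, m = len(tmpl), len(obases)
    if m > n:
        raise ValueError("oligo longer than template")

    t = _encode(tmpl)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    hits: list[tuple[int, str, int]] = []
    for strand, probe_seq in (("+", obases), ("-", revcomp(obases))):
        mm = (windows != _encode(probe_seq)).sum(axis=1)
        for start in np.nonzero(mm <= max_mismatch)[0]:
            hits.append((int(start), strand, int(mm[start])))
    hits.sort(key=lambda h: (h[2], h[0], h[1]))
    return hits


def in_silico_pcr(
    template: TemplateSeq,
    fwd: Oligo,
    rev: Oligo,
    max_mismatch: int = 0,
) -> PcrOutcome:
    """Pair a plus-strand forward-primer site with a downstream minus-strand
    reverse-primer site and extract the product (both primer footprints
    included). Multiple valid pairings are all reported; ``amplicon`` holds
    the shortest, as the kinetically favoured product."""
    fwd_hits = [h for h in find_binding_site(template, fwd, max_mismatch) if h[1] == "+"]
    rev_hits = [h for h in find_binding_site(template, rev, max_mismatch) if h[1] == "-"]
    if not fwd_hits and not rev_hits:
        return PcrOutcome("no_amplification")
    if not rev_hits:
        return PcrOutcome("fwd_only")
    if not fwd_hits:
        return PcrOutcome("rev_only")

    products = []
    for fstart, _, fmm in fwd_hits:
        for rstart, _, rmm in rev_hits:
            rend = rstart + len(rev)
            if rstart >= fstart + len(fwd):  # primers must point at each other
                products.append(
                    AmpliconResult(
                        template_id=template.id,
                        start=fstart,
                        end=rend,
                        bases=template.bases[fstart:rend],
                        fwd_mismatches=fmm,
                        rev_mismatches=rmm,
                    )
                )
    if not products:
        return PcrOutcome("no_amplification")
    products.sort(key=lambda a: (a.length, a.start))
    return PcrOutcome("ok", amplicon=products[0], products=products)


def probe_mismatch_count(amplicon: AmpliconResult | str, probe: Oligo) -> int:
    """Minimum Hamming distance between the probe and any window of either
    amplicon strand (TaqMan probes may anneal antisense)."""
    bases = amplicon.bases if isinstance(amplicon, AmpliconResult) else amplicon
    if len(probe) > len(bases):
        raise ValueError("probe longer than amplicon")
    hits = find_binding_site(TemplateSeq(id="amplicon", bases=bases), probe, len(probe))
    return min(h[2] for h in hits)


def percent_identity(a: str, b: str) -> float:
    """Global pairwise identity (match +1, mismatch 0, linear gap -1 for
    anchoring only): identical columns / alignment columns x 100."""
    if not a or not b:
        raise ValueError("empty input")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


# --- Reading the 1014 genotype off a sequenced amplicon ----------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: the codons this locus is known to segregate at position 1014
_ALLELE_CODONS = {"TTA": "L", "TTT": "F", "TCA": "S"}

#: unordered residue pairs -> genotype label
_PAIR_GENOTYPE = {
    frozenset(["L"]): "LL",
    frozenset(["F"]): "FF",
    frozenset(["L", "F"]): "LF",
    frozenset(["S", "F"]): "SF",
}


def _codon_anchor(tta_probe: Oligo, ttt_probe: Oligo) -> tuple[str, str]:
    """Derive the coding-strand flanks of the 1014 codon from the probe pair.

    The probes are antisense; they differ only across the codon, so the
    reverse complement of the TTA probe is coding-strand context with the TTA
    codon embedded, and the differing window marks where the codon sits.
    """
    sense = revcomp(tta_probe.bases)
    idx = sense.find("TTA")
    # disambiguate using the TTT probe: the same offset must read TTT
    sense_ttt = revcomp(ttt_probe.bases)
    while idx != -1 and sense_ttt[idx : idx + 3] != "TTT":
        idx = sense.find("TTA", idx + 1)
    if idx == -1:
        raise ValueError("probes do not define a discriminating codon")
    return sense[:idx], sense[idx + 3 :]


def genotype_from_sequence(
    amplicon: AmpliconResult | str,
    anchor: tuple[str, str] | None = None,
    max_flank_mismatch: int = 2,
) -> str:
    """Call the 1014 genotype from a (possibly IUPAC-ambiguous) amplicon
    sequence: LL, LF, FF, SF, or ``ambiguous``.

    ``anchor`` is the (left flank, right flank) coding-strand context of the
    codon; by default it is derived from the published probe pair. The codon
    is located at the position minimising the combined flank Hamming
    distance, tolerating up to ``max_flank_mismatch`` total mismatches (the
    more distant species the assay covers diverge at up to two probe bases).
    A Sanger trace of a heterozygote shows an ambiguity code at the varying
    position (e.g. W = A/T at the third codon position for LF).
    """
    bases = amplicon.bases if isinstance(amplicon, AmpliconResult) else amplicon.upper()
    if anchor is None:
        oligos = default_oligos()
        anchor = _codon_anchor(oligos["RTkdr_TTA"], oligos["RTkdr_TTT"])
    left, right = anchor

    best = (max_flank_mismatch + 1, None)
    for seq in (bases, revcomp(bases)):
        span = len(left) + 3 + len(right)
        for i in range(len(seq) - span + 1):
            mm = sum(a != b for a, b in zip(seq[i:], left))
            if mm >= best[0]:
                continue
            mm += sum(a != b for a, b in zip(seq[i + len(left) + 3 :], right))
            if mm < best[0]:
                best = (mm, seq[i + len(left) : i + len(left) + 3])
    codon = best[1]
    if codon is None:
        raise ValueError("codon anchor not found in amplicon")

    try:
        observed = [set(_IUPAC[b]) for b in codon]
    except KeyError:
        return "ambiguous"

    # A diploid trace shows, per position, exactly the union of the two
    # alleles' bases. Find which unordered pair of known allele codons is
    # consistent with the observed (possibly ambiguous) codon.
    alleles = list(_ALLELE_CODONS)
    matches = set()
    for i, c1 in enumerate(alleles):
        for c2 in alleles[i:]:
            if all({c1[k], c2[k]} == observed[k] for k in range(3)):
                pair = frozenset([_ALLELE_CODONS[c1], _ALLELE_CODONS[c2]])
                matches.add(_PAIR_GENOTYPE.get(pair, "ambiguous"))
    if len(matches) == 1:
        return matches.pop()
    return "ambiguous"
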