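"""UMI consensus construction, background-error polishing and ctDNA positivity.

Pipeline: read families grouped by (contig, position, UMI pair) are collapsed
into single-strand consensus sequences (SSCS, >= 2 supporting reads); SSCS
pairs with transposed UMI barcodes at the same position are merged into duplex
consensus sequences (DCS).  Candidate variants are then tested against a
position- and substitution-specific background error database with a one-sided
exact binomial test, and a sample is called ctDNA-positive when at least one
tumor-profile mutation is detected by a passing consensus mutant read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ReadFamily", "ConsensusRead", "BackgroundErrorDB", "VariantCall",
    "TumorProfile", "TissueVariant", "PlasmaCallResult",
    "build_sscs", "build_dcs", "polish_variants", "call_tissue_mutations",
    "assess_ctdna_positivity", "log_ctdna_level", "mean_vaf_from_log_level",
    "consensus_pileup", "candidate_calls",
]

#: offset of the log ctDNA transform: level = ln(mean_vaf + OFFSET) - ln(OFFSET)
LOG_CTDNA_OFFSET = 1e-6

#: floor applied when a (position, substitution) cell is absent from the db
DB_RATE_FLOOR = 1e-6


class StructuralError(ValueError):
    """Raised when read-family structure violates pipeline assumptions."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadFamily:
    """Reads sharing a mapping position and an ordered UMI pair.

    ``reads`` maps each read to its base calls: a list of dicts keyed by
    1-based genomic position.
    """
    contig: str
    position: int
    umi_a: str
    umi_b: str
    orientation: str  # "AB" or "BA"
    reads: tuple  # tuple of dict[int, str]

    def __post_init__(self):
        if self.orientation not in ("AB", "BA"):
            raise ValueError(f"orientation must be AB or BA, got {self.orientation!r}")
        if len(self.reads) < 1:
            raise ValueError("a read family needs at least one read")


@dataclass
class ConsensusRead:
    level: str  # "SSCS" or "DCS"
    contig: str
    position: int
    alleles: dict  # position -> consensus base ("N" = masked)
    support: dict  # {"AB": n, "BA": n} reads per strand orientation
    umi_a: str = ""
    umi_b: str = ""
    single_strand_flag: bool = False

    @property
    def n_reads(self) -> int:
        return sum(self.support.values())


@dataclass
class BackgroundErrorDB:
    """Per (contig, position, substitution) background error rates.

    ``substitution`` is a "REF>ALT" string.  ``rates`` maps
    (contig, position, substitution) -> error allele fraction; ``max_support``
    optionally stores the largest distinct-supporting-read count seen in
    mutation-free plasma for the same key.
    """
    rates: dict
    max_support: dict = field(default_factory=dict)
    rate_floor: float = DB_RATE_FLOOR

    def rate(self, contig, position, substitution) -> float:
        key = (contig, int(position), substitution)
        if key not in self.rates:
            logger.warning(
                "background db missing %s:%d %s; applying rate floor %.2g",
                contig, position, substitution, self.rate_floor)
            return self.rate_floor
        return max(self.rates[key], self.rate_floor)


@dataclass
class VariantCall:
    contig: str
    position: int
    ref: str
    alt: str
    depth: int            # total consensus depth at the locus
    mutant_reads: int     # unique consensus reads supporting ALT
    duplex_support: int = 0
    sscs_support: int = 0
    polish_p: float = float("nan")
    passed: bool = False

    def __post_init__(self):
        if not 0 <= self.mutant_reads <= self.depth:
            raise ValueError("mutant reads must lie in [0, depth]")

    @property
    def vaf(self) -> float:
        return self.mutant_reads / self.depth if self.depth else 0.0

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"


@dataclass(frozen=True)
class TissueVariant:
    contig: str
    position: int
    ref: str
    alt: str
    vaf: float
    supporting_reads: int
    cosmic_count: int = 0

    @property
    def hotspot(self) -> bool:
        return self.cosmic_count >= 20

    @property
    def key(self):
        return (self.contig, self.position, self.ref, self.alt)


@dataclass
class TumorProfile:
    patient: str
    mutations: list  # of TissueVariant

    def __len__(self):
        return len(self.mutations)


@dataclass
class PlasmaCallResult:
    patient: str
    draw_day: float
    detected: list          # profile mutations found in plasma (TissueVariant)
    positive: bool
    mean_vaf: float
    max_vaf: float
    unevaluable: bool = False


# ---------------------------------------------------------------------------
# consensus construction
# ---------------------------------------------------------------------------

def build_sscs(families) -> list:
    """Collapse read families into single-strand consensus reads.

    Families with fewer than two reads are dropped.  The consensus base at
    each covered locus is the per-locus majority; exact ties are masked "N".
    """
    out = []
    for fam in families:
        if len(fam.reads) < 2:
            continue
        loci = set()
        for r in fam.reads:
            loci.update(r)
        alleles = {}
        for pos in loci:
            counts = {}
            for r in fam.reads:
                b = r.get(pos)
                if b is not None:
                    counts[b] = counts.get(b, 0) + 1
            best = max(counts.values())
            winners = [b for b, c in counts.items() if c == best]
            alleles[pos] = winners[0] if len(winners) == 1 else "N"
        out.append(ConsensusRead(
            level="SSCS", contig=fam.contig, position=fam.position,
            alleles=alleles, support={fam.orientation: len(fam.reads)},
            umi_a=fam.umi_a, umi_b=fam.umi_b))
    return out


def _duplex_key(c: ConsensusRead):
    umis = (c.umi_a, c.umi_b) if c.umi_a <= c.umi_b else (c.umi_b, c.umi_a)
    return (c.contig, c.position) + umis


def build_dcs(sscs) -> list:
    """Merge SSCS pairs with transposed UMI pairs into duplex consensus reads.

    Unpartnered SSCS are retained and flagged single-strand.  Loci where the
    two strands disagree are masked "N" in the duplex consensus.  Output is
    independent of input order (sorted by position/UMI key).
    """
    groups: dict = {}
    for c in sscs:
        if c.level != "SSCS":
            raise StructuralError("build_dcs expects SSCS-level input")
        groups.setdefault(_duplex_key(c), []).append(c)
    out = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) > 2:
            raise StructuralError(
                f"{len(members)} SSCS claim duplex {key}; expected at most 2")
        if len(members) == 1:
            c = members[0]
            c.single_strand_flag = True
            out.append(c)
            continue
        a, b = members
        if (a.umi_a, a.umi_b) == (b.umi_a, b.umi_b):
            raise StructuralError(
                f"two SSCS with identical (not transposed) UMI pair at {key}")
        alleles = {}
        # loci covered by only one strand, or in disagreement, are masked
        for pos in set(a.alleles) | set(b.alleles):
            ba, bb = a.alleles.get(pos), b.alleles.get(pos)
            alleles[pos] = ba if (ba is not None and ba == bb) else "N"
        support = {"AB": 0, "BA": 0}
        for m in members:
            for o, n in m.support.items():
                support[o] += n
        out.append(ConsensusRead(
            level="DCS", contig=a.contig, position=a.position,
            alleles=alleles, support=support, umi_a=min(a.umi_a, b.umi_a),
            umi_b=max(a.umi_a, b.umi_a)))
    return out


def consensus_pileup(consensus_reads, contig, position) -> dict:
    """Per-allele consensus depth and strand-class support at one locus.

    Returns {"depth": int, "alleles": {base: {"n": .., "duplex": .., "sscs": ..}}}.
    Masked ("N") calls count toward neither depth nor any allele.
    """
    depth = 0
    alleles: dict = {}
    for c in consensus_reads:
        b = c.alleles.get(position)
        if b is None or b == "N" or c.contig != contig:
            continue
        depth += 1
        slot = alleles.setdefault(b, {"n": 0, "duplex": 0, "sscs": 0})
        slot["n"] += 1
        if c.level == "DCS":
            slot["duplex"] += 1
        else:
            slot["sscs"] += 1
    return {"depth": depth, "alleles": alleles}


def candidate_calls(consensus_reads, loci) -> list:
    """Build VariantCall candidates at the requested (contig, pos, ref, alt) loci."""
    calls = []
    for contig, position, ref, alt in loci:
        pile = consensus_pileup(consensus_reads, contig, position)
        slot = pile["alleles"].get(alt, {"n": 0, "duplex": 0, "sscs": 0})
        calls.append(VariantCall(
            contig=contig, position=position, ref=ref, alt=alt,
            depth=pile["depth"], mutant_reads=slot["n"],
            duplex_support=slot["duplex"], sscs_support=slot["sscs"]))
    return calls


# ---------------------------------------------------------------------------
# polishing and positivity
# ---------------------------------------------------------------------------

def polish_variants(candidates, db: BackgroundErrorDB, alpha: float = 0.01,
                    min_duplex: int = 1, min_sscs: int = 2) -> list:
    """Filter candidates against the background error database.

    A candidate passes when the one-sided exact binomial tail
    P(X >= mutant_reads | depth, db rate) is below ``alpha`` AND its distinct
    supporting reads satisfy the support criterion (>= ``min_duplex`` duplex
    reads, or >= ``min_sscs`` single-strand reads).  ``polish_p`` is recorded
    on every candidate; the returned list contains only the retained ones.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    retained = []
    for c in candidates:
        rate = db.rate(c.contig, c.position, c.substitution)
        if c.mutant_reads == 0 or c.depth == 0:
            c.polish_p = 1.0
            c.passed = False
            continue
        c.polish_p = float(stats.binom.sf(c.mutant_reads - 1, c.depth, rate))
        support_ok = (c.duplex_support >= min_duplex
                      or c.sscs_support >= min_sscs
                      or (c.duplex_support + c.sscs_support == 0
                          and c.mutant_reads >= min_sscs))
        c.passed = c.polish_p < alpha and support_ok
        if c.passed:
            retained.append(c)
    return retained


def call_tissue_mutations(tissue_variants, patient: str = "") -> TumorProfile:
    """Apply the tissue-calling thresholds to build the tumor profile.

    Hotspot mutations (>= 20 COSMIC cancer cases) are retained at VAF >= 1%
    with >= 5 supporting reads; all others need VAF >= 2% and >= 6 reads.
    """
    kept = []
    for v in tissue_variants:
        if v.hotspot:
            ok = v.vaf >= 0.01 and v.supporting_reads >= 5
        else:
            ok = v.vaf >= 0.02 and v.supporting_reads >= 6
        if ok:
            kept.append(v)
    return TumorProfile(patient=patient, mutations=kept)


def assess_ctdna_positivity(plasma_calls, profile: TumorProfile,
                            draw_day: float = float("nan"),
                            mean_mode: str = "tracked") -> PlasmaCallResult:
    """Tumor-informed positivity: >= 1 profile mutation with a passing call.

    ``mean_vaf`` averages over the tracked (tumor-profile) mutation set;
    undetected mutations contribute zero under the default ``tracked`` mode,
    or are excluded under ``detected`` mode.  An empty profile yields an
    unevaluable result.
    """
    if mean_mode not in ("tracked", "detected"):
        raise ValueError("mean_mode must be 'tracked' or 'detected'")
    if len(profile) == 0:
        return PlasmaCallResult(
            patient=profile.patient, draw_day=draw_day, detected=[],
            positive=False, mean_vaf=float("nan"), max_vaf=float("nan"),
            unevaluable=True)
    by_key = {(c.contig, c.position, c.ref, c.alt): c for c in plasma_calls}
    detected, vafs = [], []
    for mut in sorted(profile.mutations, key=lambda m: (m.contig, m.position)):
        call = by_key.get(mut.key)
        if call is not None and call.passed and call.mutant_reads >= 1:
            detected.append(mut)
            vafs.append(call.vaf)
        else:
            vafs.append(0.0)
    if mean_mode == "detected":
        pos_vafs = [v for v in vafs if v > 0]
        mean_vaf = float(np.mean(pos_vafs)) if pos_vafs else 0.0
    else:
        mean_vaf = float(np.mean(vafs))
    return PlasmaCallResult(
        patient=profile.patient, draw_day=draw_day, detected=detected,
        positive=len(detected) > 0, mean_vaf=mean_vaf,
        max_vaf=float(max(vafs)) if vafs else 0.0)


def log_ctdna_level(mean_vaf: float):
    """ln(mean_vaf + 1e-6) - ln(1e-6); zero iff mean_vaf is zero."""
    v = np.asarray(mean_vaf, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("mean VAF must lie in [0, 1]")
    out = np.log(v + LOG_CTDNA_OFFSET) - math.log(LOG_CTDNA_OFFSET)
    return float(out) if np.isscalar(mean_vaf) else out


def mean_vaf_from_log_level(level):
    """Inverse of :func:`log_ctdna_level`."""
    y = np.asarray(level, dtype=float)
    out = LOG_CTDNA_OFFSET * np.expm1(y)
    return float(out) if np.isscalar(level) else out
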