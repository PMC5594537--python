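"""Homology-based precursor annotation.

Candidate orthologues of a reference pre-miRNA are found by a BLAST-like
seed-and-extend local search (exact word seeds, gapped Smith-Waterman
extension, Karlin-Altschul E-values) and then screened with six acceptance
criteria commonly used for homology-based miRNA annotation:

  c1  the hit span is not more than 20 nt shorter than the query;
  c2  the mature sequence is locatable in the candidate with <= 2
      mismatches (substitutions + indel columns) to the query mature;
  c3  the candidate folds into a hairpin with the mature on one arm;
  c4  the hairpin minimum free energy is <= -15 kcal/mol (configurable);
  c5  the maximum one-sided bulge/internal-loop size in the stem is <= 12;
  c6  at most 6 mature positions are unpaired in the miRNA/miRNA* duplex.

A candidate is accepted iff all six flags hold. Accepted hits are further
grouped into paralogous loci, classified by genomic context, and screened
for transposable-element overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.optimize import brentq

from . import hairpin as hp
from ._dp import encode, sw_affine
from .formats import FeatureRecord, GenomeRecord, derive_introns, revcomp


@dataclass
class PrecursorQuery:
    """A reference pre-miRNA used as the unit of homology search."""

    id: str
    family: str
    sequence: str
    mature_interval: tuple[int, int]
    star_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        ms, me = self.mature_interval
        if not (0 <= ms < me <= len(self.sequence)):
            raise ValueError(f"{self.id}: mature interval outside sequence")
        if not (19 <= me - ms <= 25):
            raise ValueError(f"{self.id}: mature length {me - ms} outside 19-25 nt")

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature_interval[0] : self.mature_interval[1]]


@dataclass
class ScoringScheme:
    """blastn-like scoring with Karlin-Altschul statistics.

    ``lambda_`` is solved numerically from sum_ij p_i p_j exp(lambda*s_ij) = 1
    under the background frequencies; ``K`` defaults to the tabulated
    ungapped value for the +1/-2 scheme (Altschul-Gish style approximation,
    applied to the gapped search).
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 5.0  # positive cost
    gap_extend: float = 2.0
    word_size: int = 11
    K: float = 0.62
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lambda_: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        p = np.asarray(self.background)

        def f(lam: float) -> float:
            tot = 0.0
            for i in range(4):
                for j in range(4):
                    s = self.match if i == j else self.mismatch
                    tot += p[i] * p[j] * math.exp(lam * s)
            return tot - 1.0

        self.lambda_ = brentq(f, 1e-6, 10.0)

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lambda_ * score)

    def bit_score(self, score: float) -> float:
        return (self.lambda_ * score - math.log(self.K)) / math.log(2.0)


@dataclass
class Hit:
    """A genomic match of a query precursor (coordinates 0-based half-open,
    always on the plus-strand axis; minus-strand alignments are reported
    against the reverse complement)."""

    query_id: str
    chrom: str
    strand: str
    start: int
    end: int
    raw_score: float
    bit_score: float
    e_value: float
    aligned_query: str
    aligned_subject: str
    identity: float

    @property
    def subject_span(self) -> int:
        return self.end - self.start


def _alignment_strings(a: str, b: str, ai: int, bi: int, ops: np.ndarray) -> tuple[str, str]:
    qa, qb = [], []
    i, j = ai, bi
    for op in ops:
        if op == 0:
            qa.append(a[i])
            qb.append(b[j])
            i += 1
            j += 1
        elif op == 1:
            qa.append(a[i])
            qb.append("-")
            i += 1
        else:
            qa.append("-")
            qb.append(b[j])
            j += 1
    return "".join(qa), "".join(qb)


class GenomeIndex:
    """Exact-word index of both strands of a genome, built once per species."""

    def __init__(self, genome: list[GenomeRecord], word_size: int):
        if not genome:
            raise ValueError("empty genome")
        self.word_size = word_size
        self.total_len = sum(len(rec.sequence) for rec in genome)
        self.subjects: dict[tuple[str, str], str] = {}
        self.words: dict[tuple[str, str], dict[str, list[int]]] = {}
        for rec in genome:
            for strand in "+-":
                subject = rec.sequence if strand == "+" else revcomp(rec.sequence)
                index: dict[str, list[int]] = {}
                for gpos in range(len(subject) - word_size + 1):
                    word = subject[gpos : gpos + word_size]
                    if "N" in word:
                        continue
                    index.setdefault(word, []).append(gpos)
                self.subjects[(rec.chrom_id, strand)] = subject
                self.words[(rec.chrom_id, strand)] = index


def search_homologs(
    query: PrecursorQuery,
    genome: list[GenomeRecord],
    scoring: ScoringScheme | None = None,
    e_max: float = 1e-4,
    window_margin: int | None = None,
    index: GenomeIndex | None = None,
) -> list[Hit]:
    """Seed-and-extend local search of ``query`` against both genome strands.

    Exact ``word_size`` matches seed a gapped Smith-Waterman extension in a
    window around the seed diagonal; statistics follow E = K*m*n*exp(-lambda*S)
    with m the query length and n the total searched length (both strands).
    Overlapping hits on one locus are merged to the best-scoring (lowest E,
    ties by identity then leftmost). Hits are returned sorted by E-value.
    """
    scoring = scoring or ScoringScheme()
    if not genome:
        raise ValueError("empty genome")
    qseq = query.sequence.upper().replace("U", "T")
    w = scoring.word_size
    if len(qseq) < w:
        raise ValueError(f"query {query.id} shorter than word size {w}")
    margin = window_margin if window_margin is not None else 30
    qcodes = encode(qseq)
    if index is None:
        index = GenomeIndex(genome, w)
    elif index.word_size != w:
        raise ValueError("index word size does not match scoring word size")

    n_total = 2 * index.total_len
    m = len(qseq)
    hits: list[Hit] = []
    for rec in genome:
        for strand in "+-":
            subject = index.subjects[(rec.chrom_id, strand)]
            words = index.words[(rec.chrom_id, strand)]
            # collect seed diagonals, collapse nearby seeds into one window
            anchors: set[int] = set()
            for qpos in range(len(qseq) - w + 1):
                for gpos in words.get(qseq[qpos : qpos + w], ()):
                    anchors.add(gpos - qpos)
            # one extension window per group of nearby diagonals, so tandem
            # copies a short spacer apart each get their own extension
            merged: list[tuple[int, int]] = []
            group: list[int] = []
            for anchor in sorted(anchors):
                if group and anchor - group[-1] > 2 * w:
                    merged.append(
                        (max(0, group[0] - margin), min(len(subject), group[-1] + m + margin))
                    )
                    group = []
                group.append(anchor)
            if group:
                merged.append(
                    (max(0, group[0] - margin), min(len(subject), group[-1] + m + margin))
                )
            for lo, hi in merged:
                sub = subject[lo:hi]
                score, qa0, qa1, sb0, sb1, ops = sw_affine(
                    qcodes,
                    encode(sub),
                    scoring.match,
                    scoring.mismatch,
                    scoring.gap_open,
                    scoring.gap_extend,
                )
                if score <= 0:
                    continue
                e = scoring.evalue(score, m, n_total)
                if e > e_max:
                    continue
                aq, asub = _alignment_strings(qseq, sub, qa0, sb0, ops)
                ident = sum(1 for x, y in zip(aq, asub) if x == y) / max(1, len(aq))
                s_lo, s_hi = lo + sb0, lo + sb1
                if strand == "-":
                    s_lo, s_hi = len(subject) - s_hi, len(subject) - s_lo
                hits.append(
                    Hit(
                        query_id=query.id,
                        chrom=rec.chrom_id,
                        strand=strand,
                        start=s_lo,
                        end=s_hi,
                        raw_score=score,
                        bit_score=scoring.bit_score(score),
                        e_value=e,
                        aligned_query=aq,
                        aligned_subject=asub,
                        identity=ident,
                    )
                )
    return merge_hits(hits)


def merge_hits(hits: list[Hit]) -> list[Hit]:
    """Keep the best hit per locus. Overlapping spans on one chromosome are one
    locus irrespective of strand (a hairpin is near-self-complementary, so the
    search finds the same locus on both strands)."""
    kept: list[Hit] = []
    for h in sorted(hits, key=lambda h: (h.e_value, -h.identity, h.chrom, h.start)):
        if any(
            k.chrom == h.chrom and h.start < k.end and k.start < h.end for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.e_value, -h.identity, h.chrom, h.start))
    return kept


def criterion_length(hit: Hit, query: PrecursorQuery, max_shorter: int = 20) -> bool:
    """c1: the aligned subject span is at most ``max_shorter`` nt shorter than
    the query."""
    return (len(query.sequence) - hit.subject_span) <= max_shorter


def criterion_mature_mismatch(candidate_mature: str, query_mature: str) -> int:
    """c2 quantity: substitutions + indel columns in the global alignment of
    the two mature sequences (edit distance)."""
    res = edlib.align(
        candidate_mature.upper().replace("U", "T"),
        query_mature.upper().replace("U", "T"),
        mode="NW",
        task="distance",
    )
    return res["editDistance"]


@dataclass
class CandidateVerdict:
    """Six-criterion filter outcome for one hit."""

    hit: Hit
    family: str
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool
    mature_mismatches: int | None = None
    duplex_mismatch_count: int | None = None
    mfe: float | None = None
    max_bulge_size: int | None = None
    candidate_interval: tuple[int, int] | None = None  # genome coords incl. flank
    mature_interval: tuple[int, int] | None = None  # within candidate sequence
    star_interval: tuple[int, int] | None = None
    reason: str = ""
    paralogue_group: str | None = None
    context: str | None = None
    te_families: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4 and self.c5 and self.c6


@dataclass
class FilterThresholds:
    max_shorter_than_query: int = 20
    max_mature_mismatches: int = 2
    mfe_max: float = -15.0  # kcal/mol
    max_bulge: int = 12
    max_duplex_mismatches: int = 6


def evaluate_candidate(
    hit: Hit,
    query: PrecursorQuery,
    genome: dict[str, str],
    flank: int = 0,
    thresholds: FilterThresholds | None = None,
    model: hp.EnergyModel | None = None,
) -> CandidateVerdict:
    """Apply the six acceptance criteria to one hit."""
    th = thresholds or FilterThresholds()
    chrom_seq = genome[hit.chrom]
    lo = max(0, hit.start - flank)
    hi = min(len(chrom_seq), hit.end + flank)
    cand = chrom_seq[lo:hi]
    if hit.strand == "-":
        cand = revcomp(cand)

    c1 = criterion_length(hit, query, th.max_shorter_than_query)

    # locate the mature inside the candidate by infix alignment
    qmat = query.mature_seq.upper().replace("U", "T")
    loc = edlib.align(qmat, cand, mode="HW", task="locations")
    mature_iv = None
    mism = None
    c2 = False
    reason = ""
    if loc["editDistance"] >= 0 and loc["locations"]:
        s, e = loc["locations"][0]
        mature_iv = (s, e + 1)
        mism = loc["editDistance"]
        c2 = mism <= th.max_mature_mismatches
    else:
        reason = "mature-not-locatable"

    c3 = c4 = c5 = c6 = False
    mfe = None
    bulge = None
    dup = None
    star_iv = None
    try:
        structure = hp.fold_hairpin(cand, model=model)
        mfe = structure.mfe
        c4 = mfe <= th.mfe_max
        bulge = hp.max_bulge(structure)
        c5 = bulge <= th.max_bulge
        if mature_iv is not None:
            try:
                dup, star_iv = hp.duplex_mismatches(structure, mature_iv)
                c3 = structure.is_hairpin
                c6 = dup <= th.max_duplex_mismatches
            except hp.MatureInLoopError:
                reason = reason or "mature-in-terminal-loop"
    except hp.FoldError as exc:
        reason = reason or f"fold-error:{exc}"

    return CandidateVerdict(
        hit=hit,
        family=query.family,
        c1=c1,
        c2=c2,
        c3=c3,
        c4=c4,
        c5=c5,
        c6=c6,
        mature_mismatches=mism,
        duplex_mismatch_count=dup,
        mfe=mfe,
        max_bulge_size=bulge,
        candidate_interval=(lo, hi),
        mature_interval=mature_iv,
        star_interval=star_iv,
        reason=reason,
    )


def group_paralogues(
    verdicts: list[CandidateVerdict], min_locus_gap: int = 200
) -> list[CandidateVerdict]:
    """Assign paralogue-group labels to accepted verdicts of one species.

    Loci of one query are distinct paralogues when they lie on different
    chromosomes or are separated by more than ``min_locus_gap`` nt.
    """
    by_query: dict[str, list[CandidateVerdict]] = {}
    for v in verdicts:
        if v.accepted:
            by_query.setdefault(v.hit.query_id, []).append(v)
    for qid, vs in by_query.items():
        vs.sort(key=lambda v: (v.hit.chrom, v.hit.start))
        group = 0
        prev: CandidateVerdict | None = None
        for v in vs:
            if prev is not None and (
                v.hit.chrom != prev.hit.chrom or v.hit.start - prev.hit.end > min_locus_gap
            ):
                group += 1
            v.paralogue_group = f"{qid}.p{group}"
            prev = v
    return verdicts


def species_summary(verdicts: list[CandidateVerdict]) -> dict[str, float]:
    """Census-style per-species counts from accepted verdicts.

    genes = query genes with >= 1 accepted locus; hits = accepted distinct
    loci (paralogues included); averages are hits/genes and genes/families.
    """
    accepted = [v for v in verdicts if v.accepted]
    families = {v.family for v in accepted}
    genes = {v.hit.query_id for v in accepted}
    n_hits = len(accepted)
    te_families = {v.family for v in accepted if v.te_families}
    return {
        "n_families": len(families),
        "n_genes": len(genes),
        "n_hits": n_hits,
        "genes_per_family": len(genes) / len(families) if families else float("nan"),
        "paralogues_per_gene": n_hits / len(genes) if genes else float("nan"),
        "n_te_families": len(te_families),
    }


def classify_context(
    locus: tuple[str, int, int], features: list[FeatureRecord]
) -> str:
    """Classify a locus as intergenic / exonic / intronic / intron_exon.

    intergenic: no overlap with any gene; intron_exon: the locus spans at
    least one intron-exon boundary (overlaps both exon and intron sequence);
    otherwise exonic or intronic by the containing feature.
    """
    chrom, start, end = locus
    genes = [f for f in features if f.feature_kind == "gene" and f.chrom_id == chrom]
    if not any(f.start < end and start < f.end for f in genes):
        return "intergenic"
    exons = [
        f
        for f in features
        if f.feature_kind == "exon" and f.chrom_id == chrom and f.start < end and start < f.end
    ]
    introns = [
        f
        for f in features
        if f.feature_kind == "intron" and f.chrom_id == chrom and f.start < end and start < f.end
    ]
    if not introns and not any(f.feature_kind == "intron" for f in features):
        introns = [
            f
            for f in derive_introns(features)
            if f.chrom_id == chrom and f.start < end and start < f.end
        ]
    if exons and introns:
        return "intron_exon"
    if exons:
        return "exonic"
    if introns:
        return "intronic"
    return "exonic"  # gene without sub-features: treat gene body as exonic


def scan_te_overlap(
    precursor_seq: str,
    te_library: list[GenomeRecord],
    min_identity: float = 0.8,
    min_overlap: int = 50,
    scoring: ScoringScheme | None = None,
) -> list[str]:
    """TE families with a local alignment of >= ``min_overlap`` aligned
    columns at >= ``min_identity`` to the precursor (both strands searched).

    Library entry IDs carry the family label up to the last underscore
    (e.g. ``STOWAWAY_3`` -> ``STOWAWAY``).
    """
    import warnings

    scoring = scoring or ScoringScheme()
    if not te_library:
        warnings.warn("empty TE library: no TE screening performed")
        return []
    pre = precursor_seq.upper().replace("U", "T")
    pcodes = encode(pre)
    fams: list[str] = []
    for rec in te_library:
        fam = rec.chrom_id.rsplit("_", 1)[0]
        if fam in fams:
            continue
        for strand_seq in (rec.sequence, revcomp(rec.sequence)):
            score, a0, a1, b0, b1, ops = sw_affine(
                pcodes,
                encode(strand_seq),
                scoring.match,
                scoring.mismatch,
                scoring.gap_open,
                scoring.gap_extend,
            )
            ncols = len(ops)
            if ncols < min_overlap:
                continue
            i, j = a0, b0
            matches = 0
            for op in ops:
                if op == 0:
                    if pre[i] == strand_seq[j]:
                        matches += 1
                    i += 1
                    j += 1
                elif op == 1:
                    i += 1
                else:
                    j += 1
            if matches / ncols >= min_identity:
                fams.append(fam)
                break
    return fams
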