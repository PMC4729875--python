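"""Structural annotation of resolved insertions with TPRT hallmarks.

Given the left genomic flank, the inserted sequence and the right genomic
flank of a resolved insertion, this module reports the canonical hallmarks of
L1-mediated target-primed reverse transcription: the target site duplication
(TSD), the endonuclease motif score at the integration site (Hamming distance
to 5'-TTTT/AA-3' on either strand), the 3' poly-A tail length, the 5'
truncation offset into the family consensus, twin-priming inversions with
their spacer, 3' truncation, 1-5 nt microcomplementarities, and untemplated
5' nucleotides.

The inserted sequence is aligned to the family consensus with a local
affine-gap aligner (match 2, mismatch -3, open -5, extend -2); antisense
insertions are recognised by alignment orientation and canonicalised to the
element-sense frame before structural parsing.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .consensus import ConsensusLibrary
from .util import revcomp

EN_MOTIF = "TTTTAA"

DEFAULT_MAX_TSD = 30
DEFAULT_EN_BUDGET = 2       # <= 2 mismatches still "resembles" the motif
FULL_LENGTH_TOL = 3         # consensus bases
POLYA_INTERRUPTION_WINDOW = 20  # <= 1 non-A per this many bases
MIN_INVERSION_PREFIX = 10   # unaligned 5' prefix longer than this tries inversion
MAX_UNTEMPLATED = 6


@dataclass
class InsertionSequence:
    left_flank: str
    insert: str
    right_flank: str
    family: str

    def __post_init__(self):
        if not self.insert:
            raise ValueError("inserted sequence must be non-empty")


@dataclass
class HallmarkReport:
    family: str
    subfamily: str
    orientation: str              # '+' sense, '-' antisense
    tsd: str
    en_context: str
    en_mismatches: int | None     # None when context unavailable
    en_dependent: bool | None
    polya_length: int
    five_prime_truncation: int    # consensus offset of 5'-most element base
    three_prime_truncation: bool
    inversion: tuple[int, int] | None  # (breakpoint, spacer length)
    inverted_length: int
    microcomplementarity: int
    untemplated_5p: str
    full_length: bool
    notes: str = ""

    @property
    def tsd_length(self) -> int:
        return len(self.tsd)


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = 2
    aln.mismatch_score = -3
    aln.open_gap_score = -5
    aln.extend_gap_score = -2
    return aln


def detect_tsd(left_flank: str, right_flank: str,
               max_tsd: int = DEFAULT_MAX_TSD) -> str:
    """Longest exact suffix of the left flank equal to a prefix of the right.

    Returns the empty string for a blunt junction; never raises on mismatch.
    """
    limit = min(max_tsd, len(left_flank), len(right_flank))
    for k in range(limit, 0, -1):
        if left_flank[-k:] == right_flank[:k]:
            return right_flank[:k]
    return ""


def score_en_motif(context: str) -> tuple[int, str] | None:
    """Minimum Hamming distance of a 6-mer cleavage context to TTTT/AA.

    Both strand readings are scored; returns (mismatches, strand) or None
    when fewer than 6 bases of context are available.  Strand-symmetric by
    construction.
    """
    if len(context) < 6:
        return None
    ctx = context[:6].upper()
    fwd = sum(a != b for a, b in zip(ctx, EN_MOTIF))
    rev = sum(a != b for a, b in zip(revcomp(ctx), EN_MOTIF))
    return (fwd, "+") if fwd <= rev else (rev, "-")


def measure_polya(insert: str,
                  interruption_window: int = POLYA_INTERRUPTION_WINDOW) -> int:
    """Length (in A bases) of the maximal 3'-terminal poly-A tract.

    Scanning from the 3' terminus, at most one non-A base is tolerated per
    ``interruption_window`` scanned bases; the tract ends before the second
    close interruption and must terminate on an A.
    """
    n = len(insert)
    count = 0          # A bases accepted
    last_nonA = None   # scan index of the most recent tolerated interruption
    i = n - 1
    scanned = 0
    while i >= 0:
        base = insert[i]
        scanned += 1
        if base == "A":
            count += 1
        else:
            if last_nonA is not None and scanned - last_nonA < interruption_window:
                break
            if scanned == 1:  # terminal base is not A: tract cannot start here
                break
            last_nonA = scanned
        i -= 1
    # drop any tolerated interruption hanging at the 5' end of the tract
    return count


_REFINE_K = 10  # exact-match run length anchoring a refined boundary


def _best_alignment(aligner, query: str, target: str):
    """Best local alignment; returns (score, qstart, qend, tstart, tend).

    Alignment boundaries are refined to the outermost position where an
    exact ``_REFINE_K``-mer match begins, which strips chance mismatch-bridged
    extensions at junctions (a few bases of spacer or flank that happen to
    pay for themselves under the scoring scheme).
    """
    if not query or not target:
        return None
    alns = aligner.align(query, target)
    if len(alns) == 0:
        return None
    a = alns[0]
    qblocks, tblocks = a.aligned
    if len(qblocks) == 0:
        return None
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    ts, te = int(tblocks[0][0]), int(tblocks[-1][1])
    k = _REFINE_K
    off_l = int(tblocks[0][0]) - int(qblocks[0][0])
    i = qs
    while i + k <= qe and query[i:i + k] != target[i + off_l:i + off_l + k]:
        i += 1
    off_r = int(tblocks[-1][1]) - int(qblocks[-1][1])
    j = qe
    while j - k >= i and query[j - k:j] != target[j + off_r - k:j + off_r]:
        j -= 1
    if i + k <= j:  # refined anchors found on both ends
        qs, qe, ts, te = i, j, i + off_l, j + off_r
    return (a.score, qs, qe, ts, te)


def classify_structure(ins: InsertionSequence, library: ConsensusLibrary,
                       max_tsd: int = DEFAULT_MAX_TSD,
                       en_budget: int = DEFAULT_EN_BUDGET,
                       full_length_tol: int = FULL_LENGTH_TOL) -> HallmarkReport:
    """Annotate one resolved insertion with its TPRT hallmarks."""
    if ins.family not in library.families:
        raise ValueError(f"no consensus for family {ins.family!r}")
    aligner = _aligner()

    tsd = detect_tsd(ins.left_flank, ins.right_flank, max_tsd=max_tsd)

    # EN context in the genome frame.  With cleavage between motif positions
    # 4 and 5, a top-strand motif occupies [p-4, p+2) around the insertion
    # point p and a bottom-strand motif occupies [p-2, p+4); both windows are
    # scored and the closer one reported.
    left_core = ins.left_flank[:len(ins.left_flank) - len(tsd)] if tsd else ins.left_flank
    windows = [left_core[-4:] + ins.right_flank[:2],
               left_core[-2:] + ins.right_flank[:4]]
    scored = [(score_en_motif(w), w) for w in windows if len(w) == 6]
    scored = [(s, w) for s, w in scored if s is not None]
    if scored:
        (en_mm, _), context = min(scored, key=lambda sw: sw[0][0])
        en_dependent = en_mm <= en_budget
        notes = ""
    else:
        context, en_mm, en_dependent = "", None, None
        notes = "en context unavailable"

    # choose subfamily consensus and orientation by alignment score
    best = None
    for sub in library.subfamilies(ins.family):
        cons = library.sequence(ins.family, sub)
        for orient, seq in (("+", ins.insert), ("-", revcomp(ins.insert))):
            hit = _best_alignment(aligner, seq, cons)
            if hit is not None and (best is None or hit[0] > best[0][0]):
                best = (hit, sub, orient, cons, seq)
    if best is None:
        raise ValueError("inserted sequence does not align to any consensus")
    _, subfamily, orientation, cons, insert = best

    # canonical element-sense frame
    if orientation == "-":
        left = revcomp(ins.right_flank)
    else:
        left = ins.left_flank

    polya = measure_polya(insert)
    core = insert[:len(insert) - polya] if polya else insert
    body = _best_alignment(aligner, core, cons)
    if body is None:
        raise ValueError("element body does not align to the consensus")
    _, qs, qe, ts, te = body

    three_prime_trunc = te < len(cons) - 2
    inversion = None
    inverted_length = 0
    untemplated = ""
    micro = 0
    five_prime_start = ts

    prefix = core[:qs]
    if len(prefix) > MIN_INVERSION_PREFIX:
        inv = _best_alignment(aligner, revcomp(prefix), cons)
        if inv is not None and inv[0] >= 2 * MIN_INVERSION_PREFIX:
            _, iqs, iqe, its, ite = inv
            spacer_len = iqs  # revcomp(prefix) = revcomp(spacer) + cons[a:b]
            inversion = (ts, spacer_len)
            inverted_length = ite - its
            five_prime_start = its
        else:
            notes = (notes + "; " if notes else "") + "unresolved 5' prefix"
    elif prefix:
        untemplated = prefix[-MAX_UNTEMPLATED:]
    else:
        # microcomplementarity: flank suffix identical to the element 5' start
        for k in range(min(5, len(left), len(core) - qs), 0, -1):
            if left[-k:] == core[qs:qs + k]:
                micro = k
                break

    full_length = five_prime_start <= full_length_tol and inversion is None

    return HallmarkReport(
        family=ins.family, subfamily=subfamily, orientation=orientation,
        tsd=tsd, en_context=context, en_mismatches=en_mm,
        en_dependent=en_dependent, polya_length=polya,
        five_prime_truncation=five_prime_start,
        three_prime_truncation=three_prime_trunc, inversion=inversion,
        inverted_length=inverted_length, microcomplementarity=micro,
        untemplated_5p=untemplated, full_length=full_length, notes=notes)
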