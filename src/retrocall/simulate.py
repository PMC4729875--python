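"""Synthetic genomes, planted retrotransposon insertions and junction amplicons.

This module is the test bed for the whole pipeline: it generates a toy genome
with gene models, plants L1/Alu/SVA/LTR insertions carrying the structural
hallmarks of target-primed reverse transcription (TSD, poly-A tail, EN motif,
5' truncation, twin-priming inversion with optional spacer, untemplated 5'
nucleotides, EN-independent integration with 3' truncation), and emits
capture-style 5'/3' junction amplicon tables at configurable variant allele
fraction, depth and PCR-duplicate rate, together with ground-truth and
known-insertion catalog tables.

Coordinates are 0-based, half-open throughout.  The insertion point is the
index of the first base of the 3' genomic flank.  All randomness flows from
an explicit ``numpy`` generator so identical configurations are byte-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusLibrary, default_library
from .denovo import CohortDesign, SampleInfo
from .util import random_dna, revcomp

EN_MOTIF = "TTTTAA"  # L1 endonuclease target, written 5'-TTTT/AA-3'
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

READ_LENGTH = 150
JITTER = 30  # junction amplicon start jitter, +/- bases


# ---------------------------------------------------------------------------
# configuration


@dataclass
class FamilySpec:
    """Structural repertoire of one retrotransposon family in the simulator."""

    family: str
    subfamily: str
    full_length_fraction: float = 0.5
    twin_priming_fraction: float = 0.25       # among 5'-truncated events
    en_independent_fraction: float = 0.1
    tsd_length_range: tuple[int, int] = (4, 20)
    polya_length_range: tuple[int, int] = (10, 60)
    untemplated_nt_probability: float = 0.15  # full-length events only
    spacer_probability: float = 0.5           # among twin-priming events
    spacer_length: int = 25                   # mirrors the 25-bp unknown fragment

    def validate(self) -> None:
        for name in ("full_length_fraction", "twin_priming_fraction",
                     "en_independent_fraction", "untemplated_nt_probability",
                     "spacer_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("tsd_length_range", "polya_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} is empty or negative: {(lo, hi)}")
        if self.spacer_length < 0:
            raise ValueError("spacer_length must be >= 0")


def default_family_specs() -> list[FamilySpec]:
    return [
        FamilySpec("L1", "L1-Ta"),
        FamilySpec("L1", "L1-preTa", full_length_fraction=0.3),
        FamilySpec("Alu", "AluYa5", full_length_fraction=0.9,
                   twin_priming_fraction=0.0, untemplated_nt_probability=0.0),
        FamilySpec("Alu", "AluYb8", full_length_fraction=0.9,
                   twin_priming_fraction=0.0, untemplated_nt_probability=0.0),
        FamilySpec("SVA", "SVA_E", full_length_fraction=0.6,
                   twin_priming_fraction=0.0, untemplated_nt_probability=0.0),
        FamilySpec("LTR", "LTR", full_length_fraction=1.0,
                   twin_priming_fraction=0.0, en_independent_fraction=1.0,
                   untemplated_nt_probability=0.0),
    ]


@dataclass
class SimConfig:
    genome_length: int = 300_000
    n_chromosomes: int = 2
    n_genes: int = 30
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    gc_content: float = 0.41
    families: list[FamilySpec] = field(default_factory=default_family_specs)
    vaf: float = 1.0
    depth: float = 30.0          # expected unique amplicons per junction at VAF 1
    duplicate_rate: float = 0.15
    seed: int = 1
    en_mismatch_budget: int = 1

    def validate(self) -> None:
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"vaf must lie in (0, 1], got {self.vaf}")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        lo, hi = self.gene_length_range
        if lo > hi or lo <= 0:
            raise ValueError("gene_length_range is empty")
        if self.n_chromosomes < 1 or self.genome_length < self.n_chromosomes:
            raise ValueError("need at least one base per chromosome")
        for spec in self.families:
            spec.validate()


# ---------------------------------------------------------------------------
# genome


@dataclass
class SimGenome:
    """Toy genome: chromosome sequences plus 0-based half-open gene models."""

    chromosomes: dict[str, str]
    genes: pd.DataFrame  # columns: chrom, start, end, name, score, strand, tss

    def __post_init__(self):
        self._en_cache: dict[int, list[tuple[str, int, str]]] = {}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


GENE_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "tss"]


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimGenome:
    """Generate chromosome sequences and non-overlapping gene models."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    per = config.genome_length // config.n_chromosomes
    chroms = {f"chr{i + 1}": random_dna(rng, per, gc=config.gc_content)
              for i in range(config.n_chromosomes)}

    lo, hi = config.gene_length_range
    if config.n_genes * lo > config.genome_length:
        raise ValueError("gene demand exceeds genome capacity")
    rows = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    names = list(chroms)
    for g in range(config.n_genes):
        for attempt in range(2000):
            chrom = names[int(rng.integers(len(names)))]
            length = int(rng.integers(lo, hi + 1))
            if length >= len(chroms[chrom]):
                continue
            start = int(rng.integers(0, len(chroms[chrom]) - length))
            end = start + length
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                tss = start if strand == "+" else end - 1
                rows.append((chrom, start, end, f"gene{g + 1}", 0, strand, tss))
                break
        else:
            raise ValueError("gene demand exceeds genome capacity (placement failed)")
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return SimGenome(chromosomes=chroms, genes=genes)


# ---------------------------------------------------------------------------
# integration sites


@dataclass(frozen=True)
class Site:
    chrom: str
    position: int       # insertion point: first base of the 3' flank
    strand: str         # strand carrying the EN motif / element orientation
    motif_context: str  # 6-mer read on `strand`, slash between positions 4 and 5
    en_dependent: bool


def _window_mismatches(arr: np.ndarray, motif: str) -> np.ndarray:
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    k = len(m)
    out = np.zeros(len(arr) - k + 1, dtype=np.int16)
    for j in range(k):
        out += arr[j: len(arr) - k + 1 + j] != m[j]
    return out


def scan_en_sites(genome: SimGenome, mismatch_budget: int,
                  margin: int = 200) -> list[tuple[str, int, str]]:
    """All (chrom, insertion_point, strand) with an EN motif within budget.

    The motif 5'-TTTT/AA-3' is scanned on both strands; the cleavage position
    (between motif positions 4 and 5) maps to the returned insertion point.
    """
    key = mismatch_budget
    if key in genome._en_cache:
        return genome._en_cache[key]
    sites: list[tuple[str, int, str]] = []
    rc_motif = revcomp(EN_MOTIF)  # bottom-strand occurrence read on top
    for chrom, seq in genome.chromosomes.items():
        if len(seq) < 6:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        top = np.nonzero(_window_mismatches(arr, EN_MOTIF) <= mismatch_budget)[0]
        bot = np.nonzero(_window_mismatches(arr, rc_motif) <= mismatch_budget)[0]
        for i in top:
            p = int(i) + 4
            if margin <= p <= len(seq) - margin:
                sites.append((chrom, p, "+"))
        for j in bot:
            p = int(j) + 2
            if margin <= p <= len(seq) - margin:
                sites.append((chrom, p, "-"))
    sites.sort()
    genome._en_cache[key] = sites
    return sites


def motif_context(genome: SimGenome, chrom: str, position: int, strand: str) -> str:
    """6-mer around the cleavage point, read on ``strand``."""
    seq = genome.chromosomes[chrom]
    window = seq[position - 4: position + 2]
    return window if strand == "+" else revcomp(seq[position - 2: position + 4])


def select_integration_site(genome: SimGenome, en_dependent: bool,
                            mismatch_budget: int, rng: np.random.Generator,
                            margin: int = 200) -> Site:
    """Draw an integration site, EN-motif-guided or uniform."""
    if not genome.chromosomes or genome.total_length == 0:
        raise ValueError("genome is empty")
    if en_dependent:
        sites = scan_en_sites(genome, mismatch_budget, margin=margin)
        if not sites:
            raise ValueError("no integration site satisfies the EN motif budget")
        chrom, pos, strand = sites[int(rng.integers(len(sites)))]
    else:
        names = list(genome.chromosomes)
        weights = np.array([len(genome.chromosomes[c]) for c in names], dtype=float)
        chrom = names[int(rng.choice(len(names), p=weights / weights.sum()))]
        pos = int(rng.integers(margin, len(genome.chromosomes[chrom]) - margin))
        strand = "+" if rng.random() < 0.5 else "-"
    return Site(chrom, pos, strand, motif_context(genome, chrom, pos, strand),
                en_dependent)


# ---------------------------------------------------------------------------
# planting insertions


@dataclass
class TruthInsertion:
    """Ground truth for one planted insertion; mirrors the emitted sequence."""

    id: str
    family: str
    subfamily: str
    chrom: str
    position: int                 # 0-based insertion point
    strand: str
    tsd: str                      # genome-frame duplicated sequence
    en_dependent: bool
    en_motif_context: str
    five_prime_start: int         # consensus offset of the 5'-most element base
    inversion_breakpoint: int | None  # consensus coord where the sense body starts
    spacer: str                   # inverted-segment/body spacer, '' if absent
    three_prime_end: int          # consensus coord where the body ends (exclusive)
    polya_length: int
    untemplated_5p: str
    vaf: float
    is_germline: bool = False

    @property
    def tsd_length(self) -> int:
        return len(self.tsd)

    @property
    def has_inversion(self) -> bool:
        return self.inversion_breakpoint is not None

    @property
    def inverted_length(self) -> int:
        return (self.inversion_breakpoint - self.five_prime_start
                if self.has_inversion else 0)


FULL_LENGTH_TOLERANCE = 3  # consensus bases; accommodates untemplated additions


def build_cassette(truth: TruthInsertion, library: ConsensusLibrary) -> str:
    """Element-sense inserted sequence implied by a truth record."""
    cons = library.sequence(truth.family, truth.subfamily)
    if truth.five_prime_start >= len(cons) or truth.three_prime_end > len(cons):
        raise ValueError("truncation offset beyond consensus length")
    parts = [truth.untemplated_5p]
    if truth.has_inversion:
        parts.append(revcomp(cons[truth.five_prime_start:truth.inversion_breakpoint]))
        parts.append(truth.spacer)
        body_start = truth.inversion_breakpoint
    else:
        body_start = truth.five_prime_start
    parts.append(cons[body_start:truth.three_prime_end])
    parts.append("A" * truth.polya_length)
    return "".join(parts)


def inserted_sequence(truth: TruthInsertion, library: ConsensusLibrary) -> str:
    """Genome-frame inserted sequence (reverse-complemented on '-' strand)."""
    cassette = build_cassette(truth, library)
    return cassette if truth.strand == "+" else revcomp(cassette)


def _draw_spacer(rng, length, cons, a, b):
    """Spacer whose junction bases cannot extend an exact alignment by chance."""
    for _ in range(100):
        spacer = random_dna(rng, length)
        ok_left = a == 0 or spacer[0] != _COMP[cons[a - 1]]
        ok_right = spacer[-1] != cons[b - 1]
        if ok_left and ok_right:
            return spacer
    raise RuntimeError("could not draw an unambiguous spacer")


def plant_insertion(genome: SimGenome, spec: FamilySpec, site: Site,
                    rng: np.random.Generator, library: ConsensusLibrary,
                    vaf: float = 1.0, ins_id: str = "ins1",
                    is_germline: bool = False, tsd_length: int | None = None,
                    emit_haplotype: bool = True) -> tuple[TruthInsertion, str | None]:
    """Plant one insertion at ``site``; return truth and the modified haplotype.

    The haplotype is ``left flank + TSD + inserted sequence + right flank``
    where the right flank begins with the TSD source sequence, so the TSD
    appears twice.  The truth record fully determines the emitted sequence
    (``build_cassette``); the haplotype is optional bookkeeping.
    """
    spec.validate()
    if not 0.0 < vaf <= 1.0:
        raise ValueError(f"vaf must lie in (0, 1], got {vaf}")
    cons = library.sequence(spec.family, spec.subfamily)
    seq = genome.chromosomes[site.chrom]
    p = site.position

    full = rng.random() < spec.full_length_fraction
    inversion_breakpoint = None
    spacer = ""
    if full:
        a = 0
    else:
        a = int(rng.integers(int(0.1 * len(cons)), int(0.7 * len(cons))))
        if rng.random() < spec.twin_priming_fraction:
            inv_len = int(rng.integers(20, 121))
            b = min(a + inv_len, len(cons) - 100)
            if b <= a + 10:
                b = a + 20
            if rng.random() < spec.spacer_probability and spec.spacer_length > 0:
                spacer = _draw_spacer(rng, spec.spacer_length, cons, a, b)
            else:
                # avoid chance junction extension between inverted segment and body
                for _ in range(50):
                    if _COMP[cons[a]] != cons[b - 1]:
                        break
                    b += 1
            inversion_breakpoint = b

    three_prime_end = len(cons)
    if not site.en_dependent:
        # EN-independent integration: 3' truncated within the poly-A signal
        for _ in range(200):
            cut = len(cons) - int(rng.integers(5, 41))
            if "A" not in cons[cut - 2:cut] and cut > a + 50:
                three_prime_end = cut
                break

    polya_length = int(rng.integers(spec.polya_length_range[0],
                                    spec.polya_length_range[1] + 1))

    if tsd_length is None:
        tsd_length = int(rng.integers(spec.tsd_length_range[0],
                                      spec.tsd_length_range[1] + 1))
    tsd = seq[p:p + tsd_length]

    untemplated = ""
    if (a == 0 and inversion_breakpoint is None
            and rng.random() < spec.untemplated_nt_probability):
        candidate = "G" * int(rng.integers(1, 3))
        # adjacent flank base in the element-sense frame must differ from 'G'
        if site.strand == "+":
            adjacent = tsd[-1] if tsd else (seq[p - 1] if p else "")
        else:
            adjacent = _COMP[tsd[0]] if tsd else _COMP[seq[p]]
        if adjacent != "G":
            untemplated = candidate

    truth = TruthInsertion(
        id=ins_id, family=spec.family, subfamily=spec.subfamily,
        chrom=site.chrom, position=p, strand=site.strand, tsd=tsd,
        en_dependent=site.en_dependent, en_motif_context=site.motif_context,
        five_prime_start=a, inversion_breakpoint=inversion_breakpoint,
        spacer=spacer, three_prime_end=three_prime_end,
        polya_length=polya_length, untemplated_5p=untemplated, vaf=vaf,
        is_germline=is_germline)

    haplotype = None
    if emit_haplotype:
        haplotype = seq[:p] + tsd + inserted_sequence(truth, library) + seq[p:]
    return truth, haplotype


def truth_triplet(truth: TruthInsertion, genome: SimGenome,
                  library: ConsensusLibrary, flank: int = 120):
    """(left flank incl. TSD, inserted sequence, right flank) for annotation."""
    seq = genome.chromosomes[truth.chrom]
    p = truth.position
    left = seq[max(0, p - flank):p] + truth.tsd
    right = seq[p:p + flank]
    return left, inserted_sequence(truth, library), right


# ---------------------------------------------------------------------------
# junction amplicon libraries

READ_COLUMNS = ["read_id", "sample", "chrom", "start", "end", "strand", "side",
                "family", "elem_offset", "diag", "dup_group", "truth_id"]


def simulate_library(genome: SimGenome, truths: list[TruthInsertion],
                     config: SimConfig, rng: np.random.Generator,
                     sample_id: str = "S1",
                     library: ConsensusLibrary | None = None) -> pd.DataFrame:
    """Emit 5'/3' junction amplicons for each truth insertion.

    The expected number of insertion-supporting *unique* amplicons per
    junction is ``depth * vaf`` (Poisson).  Unique amplicons of one junction
    have distinct alignment starts jittered uniformly within +/-30 bases of
    the junction; PCR duplicates replicate a unique amplicon under a shared
    duplicate-group id (geometric multiplicity with mean 1/(1-duplicate_rate)).
    """
    config.validate()
    library = default_library() if library is None else library
    rows = []
    counter = itertools.count(1)
    offsets = np.arange(-JITTER, JITTER + 1)
    for truth in truths:
        if not 0.0 < truth.vaf <= 1.0:
            raise ValueError(f"vaf must lie in (0, 1], got {truth.vaf}")
        diag = library.diag_bases(truth.family, truth.subfamily)
        for side in ("5p", "3p"):
            n_unique = int(rng.poisson(config.depth * truth.vaf))
            n_unique = min(n_unique, len(offsets))
            if n_unique == 0:
                continue
            offs = rng.choice(offsets, size=n_unique, replace=False)
            for off in np.sort(offs):
                if side == "3p":
                    start = truth.position + int(off)
                else:
                    start = truth.position - READ_LENGTH + int(off)
                dup_group = f"{sample_id}:{truth.id}:{side}:{start}"
                if config.duplicate_rate > 0:
                    mult = int(rng.geometric(1.0 - config.duplicate_rate))
                else:
                    mult = 1
                elem_offset = (truth.five_prime_start if side == "5p"
                               else truth.three_prime_end)
                for _ in range(mult):
                    rows.append((f"r{next(counter)}", sample_id, truth.chrom,
                                 start, start + READ_LENGTH, truth.strand, side,
                                 truth.family, elem_offset, diag, dup_group,
                                 truth.id))
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    return reads.sort_values(["chrom", "start", "side", "read_id"],
                             kind="mergesort").reset_index(drop=True)


def truth_table(truths: list[TruthInsertion]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append({
            "id": t.id, "family": t.family, "subfamily": t.subfamily,
            "chrom": t.chrom, "position": t.position, "strand": t.strand,
            "tsd": t.tsd, "tsd_length": t.tsd_length,
            "en_dependent": t.en_dependent,
            "en_motif_context": t.en_motif_context,
            "five_prime_start": t.five_prime_start,
            "inversion_breakpoint": (-1 if t.inversion_breakpoint is None
                                     else t.inversion_breakpoint),
            "spacer_length": len(t.spacer),
            "three_prime_end": t.three_prime_end,
            "polya_length": t.polya_length,
            "untemplated_5p": t.untemplated_5p, "vaf": t.vaf,
            "is_germline": t.is_germline,
        })
    return pd.DataFrame(rows)


def catalog_table(truths: list[TruthInsertion]) -> pd.DataFrame:
    """BED-like catalog of the germline-labelled subset."""
    rows = [(t.chrom, t.position, t.position + max(1, t.tsd_length),
             t.family, 0, t.strand)
            for t in truths if t.is_germline]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSim:
    """A simulated multi-sample cohort with labelled truth classes."""

    genome: SimGenome
    library: ConsensusLibrary
    design: CohortDesign
    truths: dict[str, TruthInsertion]          # id -> truth
    truth_class: dict[str, str]                # id -> germline|parental_private|
    #                                            pluripotent_private|recurrent
    sample_truths: dict[str, list[str]]        # sample -> truth ids present
    reads: dict[str, pd.DataFrame]             # sample -> amplicon table
    catalog: pd.DataFrame


def default_cohort_design() -> CohortDesign:
    samples = {
        "fibro": SampleInfo(role="parental", line="fibro"),
        "iPS-A_p12": SampleInfo(role="hipsc", line="iPS-A", passage=12,
                                parent_sample="fibro"),
        "iPS-A_p30": SampleInfo(role="hipsc", line="iPS-A", passage=30,
                                parent_sample="fibro"),
        "iPS-B_p20": SampleInfo(role="hipsc", line="iPS-B", passage=20,
                                parent_sample="fibro"),
        "ES-1_p25": SampleInfo(role="hesc", line="ES-1", passage=25),
        "ES-1_p60": SampleInfo(role="hesc", line="ES-1", passage=60),
    }
    return CohortDesign(samples=samples)


def simulate_cohort(config: SimConfig, rng: np.random.Generator | None = None,
                    design: CohortDesign | None = None,
                    n_germline: int = 12, n_parental_private: int = 4,
                    n_pluripotent_private: int = 3, n_recurrent: int = 1,
                    pluripotent_vaf: float | None = None,
                    min_site_distance: int = 600) -> CohortSim:
    """Simulate a reprogramming cohort with labelled insertion classes.

    * ``germline``: present in every sample and listed in the catalog.
    * ``parental_private``: in the parental sample and all its derived lines.
    * ``pluripotent_private``: de novo truth — in every passage of one hiPSC
      line, or only in the *later* passage of the hESC line.
    * ``recurrent``: planted independently in two different pluripotent lines
      (an artifact class exercised by the recurrence filter).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    design = default_cohort_design() if design is None else design
    genome = generate_genome(config, rng)
    library = default_library()

    parental = [s for s, info in design.samples.items() if info.role == "parental"]
    pluripotent = [s for s, info in design.samples.items() if info.role != "parental"]
    lines = sorted({design.samples[s].line for s in pluripotent})

    used: list[tuple[str, int]] = []

    def fresh_site(spec_is_en: bool) -> Site:
        for _ in range(500):
            site = select_integration_site(genome, spec_is_en,
                                           config.en_mismatch_budget, rng)
            if all(c != site.chrom or abs(site.position - q) >= min_site_distance
                   for c, q in used):
                used.append((site.chrom, site.position))
                return site
        raise RuntimeError("could not place insertions with requested spacing")

    counter = itertools.count(1)
    truths: dict[str, TruthInsertion] = {}
    truth_class: dict[str, str] = {}
    sample_truths: dict[str, list[str]] = {s: [] for s in design.samples}

    def plant(klass: str, samples: list[str], vaf: float,
              is_germline: bool) -> TruthInsertion:
        spec = config.families[int(rng.integers(len(config.families)))]
        en = rng.random() >= spec.en_independent_fraction
        site = fresh_site(en)
        ins_id = f"{klass[:2]}{next(counter)}"
        truth, _ = plant_insertion(genome, spec, site, rng, library, vaf=vaf,
                                   ins_id=ins_id, is_germline=is_germline,
                                   emit_haplotype=False)
        truths[ins_id] = truth
        truth_class[ins_id] = klass
        for s in samples:
            sample_truths[s].append(ins_id)
        return truth

    for _ in range(n_germline):
        plant("germline", list(design.samples), 1.0, True)
    for par in parental:
        derived = [s for s in pluripotent
                   if design.samples[s].parent_sample == par]
        for _ in range(n_parental_private):
            plant("parental_private", [par] + derived, 1.0, False)

    vaf_dn = config.vaf if pluripotent_vaf is None else pluripotent_vaf
    for line in lines:
        line_samples = sorted([s for s in pluripotent
                               if design.samples[s].line == line],
                              key=lambda s: design.samples[s].passage or 0)
        role = design.samples[line_samples[0]].role
        for _ in range(n_pluripotent_private):
            # hESC-private events appear only in the later passage (culture-
            # acquired); hiPSC-private events are carried by every passage.
            carriers = [line_samples[-1]] if role == "hesc" else line_samples
            plant("pluripotent_private", carriers, vaf_dn, False)

    for _ in range(n_recurrent):
        if len(lines) >= 2:
            pair = rng.choice(len(lines), size=2, replace=False)
            carriers = [s for s in pluripotent
                        if design.samples[s].line in (lines[pair[0]], lines[pair[1]])]
            plant("recurrent", carriers, 1.0, False)

    reads = {}
    for sample in design.samples:
        sample_list = [truths[i] for i in sample_truths[sample]]
        reads[sample] = simulate_library(genome, sample_list, config, rng,
                                         sample_id=sample, library=library)
    catalog = catalog_table(list(truths.values()))
    return CohortSim(genome=genome, library=library, design=design,
                     truths=truths, truth_class=truth_class,
                     sample_truths=sample_truths, reads=reads, catalog=catalog)
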