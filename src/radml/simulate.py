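"""RAD-seq read simulator with an explicit truth table.

The simulator emulates reduced-representation sequencing of a diploid: tags
are extracted from both flanks of every restriction site, heterozygous sites
are introduced at a fixed per-base rate, and each allele is sequenced to a
Poisson-distributed depth with substitution errors whose per-base probability
rises linearly along the read (zero at the first base, twice the mean at the
last). Every emitted read ID encodes its locus of origin, so downstream calls
can be scored exactly.

A built-in synthetic-genome generator plants divergent repeat families
(copy number >= 2) carrying restriction sites, which is what produces
composite read clusters after de novo clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_qc import BASES, ReadRecord, _read_tsv, _write_tsv

_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGT", "TGCA")


class MotifError(ValueError):
    """The restriction motif contains unsupported (ambiguity) characters."""


class PlacementError(ValueError):
    """Repeat families cannot be placed in the requested genome."""


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _decode(codes: np.ndarray) -> str:
    return codes.tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Parameters of one simulated sequencing experiment.

    ``mean_depth`` is the per-locus mean coverage C; each of the two alleles
    is sequenced at Poisson(C/2) so a locus totals ~C, matching the site-level
    Poisson depth model. ``per_allele_depth`` overrides the per-allele mean.
    """

    read_length: int = 35
    mean_depth: float = 30.0
    snp_rate: float = 0.005
    mean_error_rate: float = 0.01
    error_profile: str = "linear_ramp"
    enzyme_motif: str = "GAATTC"
    replicates: int = 10
    seed: int = 0
    per_allele_depth: float | None = None
    both_flanks: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.snp_rate < 1):
            raise ValueError("snp_rate must be in [0, 1)")
        if not (0 <= self.mean_error_rate < 1):
            raise ValueError("mean_error_rate must be in [0, 1)")
        if self.read_length < len(self.enzyme_motif):
            raise ValueError("read_length shorter than the enzyme motif")
        if self.error_profile != "linear_ramp":
            raise ValueError(f"unknown error profile {self.error_profile!r}")


@dataclass
class SyntheticGenomeConfig:
    """Recipe for a desk-scale genome with planted repeat families.

    ``repeat_fraction`` is the proportion of genome bases inside repeat
    copies; each family derives its copies from one template (with per-base
    ``repeat_divergence``) and carries the enzyme motif planted at the
    template centre so that composite clusters arise downstream.

    ``family_count`` overrides the family number otherwise derived from
    ``repeat_fraction``. With ``motif_free_background=True`` natural motif
    occurrences are scrubbed and exactly ``planted_unique_sites`` motifs are
    planted in the unique background, which pins the composite-cluster
    fraction to family_count / (family_count + planted_unique_sites).
    """

    genome_length: int = 1_000_000
    repeat_fraction: float = 0.35
    family_copy_numbers: Sequence[int] = (2, 3)
    repeat_divergence: float = 0.01
    gc_content: float = 0.4
    seed: int = 0
    template_length: int = 3000
    motif: str = "GAATTC"
    family_count: int | None = None
    motif_free_background: bool = False
    planted_unique_sites: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.repeat_fraction <= 1):
            raise ValueError("repeat_fraction must be in [0, 1]")
        if any(c < 2 for c in self.family_copy_numbers):
            raise ValueError("repeat family copy numbers must be >= 2")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class RepeatCopy:
    """Annotation of one placed repeat copy (0-based half-open)."""

    chrom: str
    start: int
    end: int
    family_id: int
    copy_index: int
    copy_number: int


@dataclass
class TagLocus:
    """One RAD tag locus: a read-length window anchored at a restriction site."""

    locus_id: int
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    family_id: int = 0       # 0 = unique background
    copy_number: int = 1


@dataclass
class DiploidLocus:
    """A tag locus after diploidization: two alleles plus its true genotype."""

    locus: TagLocus
    allele1: str
    allele2: str
    het_positions: dict[int, tuple[str, str]] = field(default_factory=dict)


@dataclass
class TruthTable:
    """Ground truth for a simulated read set: loci, repeat membership, genotypes."""

    loci: list[DiploidLocus]

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def by_id(self) -> dict[int, DiploidLocus]:
        return {d.locus.locus_id: d for d in self.loci}

    def snp_set(self) -> set[tuple[int, int]]:
        """All true heterozygous (locus_id, position) pairs."""
        return {(d.locus.locus_id, p) for d in self.loci for p in d.het_positions}

    def to_tsv(self, path: str | Path) -> None:
        header = ["locus_id", "chrom", "start", "end", "strand", "family_id",
                  "copy_number", "het_positions"]

        def rows():
            for d in self.loci:
                het = ",".join(f"{p}:{a}:{b}" for p, (a, b) in sorted(d.het_positions.items()))
                t = d.locus
                yield [t.locus_id, t.chrom, t.start, t.end, t.strand,
                       t.family_id, t.copy_number, het or "."]

        _write_tsv(path, header, rows())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = _read_tsv(path)
        loci = []
        for _, r in df.iterrows():
            het: dict[int, tuple[str, str]] = {}
            if str(r["het_positions"]) != ".":
                for item in str(r["het_positions"]).split(","):
                    p, a, b = item.split(":")
                    het[int(p)] = (a, b)
            tag = TagLocus(int(r["locus_id"]), str(r["chrom"]), int(r["start"]),
                           int(r["end"]), str(r["strand"]), sequence="",
                           family_id=int(r["family_id"]), copy_number=int(r["copy_number"]))
            loci.append(DiploidLocus(locus=tag, allele1="", allele2="", het_positions=het))
        return cls(loci)


def parse_read_locus(read_id: str) -> int:
    """Recover the truth locus ID encoded in a simulated read ID."""
    if not read_id.startswith("L"):
        raise ValueError(f"read id {read_id!r} does not encode a locus")
    return int(read_id[1:].split("|", 1)[0])


# ---------------------------------------------------------------------------
# Restriction sites and tag extraction
# ---------------------------------------------------------------------------

def find_restriction_sites(genome: dict[str, str], motif: str) -> dict[str, list[int]]:
    """Forward-strand occurrences (0-based starts) of the motif per sequence.

    Overlapping occurrences are all reported; palindromic motifs are counted
    once per position.
    """
    motif = motif.upper()
    if not motif or any(b not in BASES for b in motif):
        raise MotifError(f"unsupported motif {motif!r}: only A/C/G/T allowed")
    out: dict[str, list[int]] = {}
    for name, seq in genome.items():
        hits, start = [], seq.find(motif)
        while start != -1:
            hits.append(start)
            start = seq.find(motif, start + 1)
        out[name] = hits
    return out


def extract_tags(genome: dict[str, str], sites: dict[str, list[int]],
                 read_length: int, annotation: Sequence[RepeatCopy] = (),
                 both_flanks: bool = True, motif_length: int = 6) -> list[TagLocus]:
    """Extract read-length tags flanking each restriction site.

    The forward tag starts at the site; the reverse tag is the reverse
    complement of the window ending at the motif's last base, so with a
    palindromic enzyme both tags begin with the motif. Tags running off a
    sequence end are dropped. Repeat membership is taken from ``annotation``
    (a tag is repeat-derived when fully inside a repeat copy).
    """
    by_chrom: dict[str, list[RepeatCopy]] = {}
    for cp in annotation:
        by_chrom.setdefault(cp.chrom, []).append(cp)
    for copies in by_chrom.values():
        copies.sort(key=lambda c: c.start)

    def membership(chrom: str, start: int, end: int) -> tuple[int, int]:
        for cp in by_chrom.get(chrom, ()):
            if cp.start <= start and end <= cp.end:
                return cp.family_id, cp.copy_number
            if cp.start > start:
                break
        return 0, 1

    tags: list[TagLocus] = []
    next_id = 0
    for chrom, starts in sites.items():
        seq = genome[chrom]
        for s in starts:
            # forward flank
            if s + read_length <= len(seq):
                fam, cn = membership(chrom, s, s + read_length)
                tags.append(TagLocus(next_id, chrom, s, s + read_length, "+",
                                     seq[s: s + read_length], fam, cn))
                next_id += 1
            # reverse flank: window ending at the motif's last base
            if both_flanks:
                lo = s + motif_length - read_length
                if lo >= 0:
                    fam, cn = membership(chrom, lo, s + motif_length)
                    tags.append(TagLocus(next_id, chrom, lo, s + motif_length, "-",
                                         _revcomp(seq[lo: s + motif_length]), fam, cn))
                    next_id += 1
    return tags


# ---------------------------------------------------------------------------
# Diploidization and read sampling
# ---------------------------------------------------------------------------

def diploidize(tags: Sequence[TagLocus], snp_rate: float,
               rng: np.random.Generator) -> tuple[list[DiploidLocus], TruthTable]:
    """Make each tag diploid: every position turns heterozygous with prob ``snp_rate``.

    The alternate base is uniform over the three others. Returns the diploid
    loci and the truth table recording every heterozygous position.
    """
    if not (0 <= snp_rate <= 1):
        raise ValueError("snp_rate must be in [0, 1]")
    loci: list[DiploidLocus] = []
    for tag in tags:
        codes = _encode(tag.sequence)
        L = len(codes)
        het_mask = rng.random(L) < snp_rate
        allele2 = codes.copy()
        het: dict[int, tuple[str, str]] = {}
        if het_mask.any():
            idx = np.flatnonzero(het_mask)
            base_idx = np.array([_CODE[chr(c)] for c in codes[idx]])
            alt_idx = (base_idx + rng.integers(1, 4, size=idx.size)) % 4
            for pos, bi, ai in zip(idx, base_idx, alt_idx):
                het[int(pos)] = (BASES[bi], BASES[ai])
                allele2[pos] = ord(BASES[ai])
        loci.append(DiploidLocus(tag, tag.sequence, _decode(allele2), het))
    return loci, TruthTable(loci)


def _error_profile(L: int, mean_error: float) -> np.ndarray:
    """Per-position substitution probability: linear ramp, mean preserved."""
    if L == 1:
        return np.array([mean_error])
    p = np.arange(L, dtype=float)
    return 2.0 * mean_error * p / (L - 1)


def sample_reads(loci: Sequence[DiploidLocus], config: SimConfig,
                 rng: np.random.Generator) -> list[ReadRecord]:
    """Sequence each allele to Poisson depth with ramped substitution errors.

    Read IDs are ``L<locus>|A<allele>|<serial>`` so every read resolves to
    exactly one truth locus.
    """
    per_allele = (config.per_allele_depth if config.per_allele_depth is not None
                  else config.mean_depth / 2.0)
    L = config.read_length
    err = _error_profile(L, config.mean_error_rate)

    alleles: list[tuple[int, int, np.ndarray]] = []
    for d in loci:
        for k, seq in ((1, d.allele1), (2, d.allele2)):
            if len(seq) != L:
                raise ValueError("allele length does not match read_length")
            alleles.append((d.locus.locus_id, k, _encode(seq)))

    depths = rng.poisson(per_allele, size=len(alleles))
    total = int(depths.sum())
    if total == 0:
        return []
    mat = np.empty((total, L), dtype=np.uint8)
    ids: list[str] = []
    row = 0
    for (locus_id, k, codes), dep in zip(alleles, depths):
        if dep == 0:
            continue
        mat[row: row + dep] = codes
        ids.extend(f"L{locus_id}|A{k}|{j}" for j in range(dep))
        row += dep

    if config.mean_error_rate > 0:
        mask = rng.random((total, L)) < err[None, :]
        n_err = int(mask.sum())
        if n_err:
            flat = mat[mask]
            base_idx = np.empty(n_err, dtype=np.int64)
            for b, i in _CODE.items():
                base_idx[flat == ord(b)] = i
            alt = (base_idx + rng.integers(1, 4, size=n_err)) % 4
            mat[mask] = np.frombuffer("ACGT".encode(), dtype=np.uint8)[alt]

    return [ReadRecord(id=rid, sequence=mat[i].tobytes().decode())
            for i, rid in enumerate(ids)]


# ---------------------------------------------------------------------------
# Synthetic genome with planted repeat families
# ---------------------------------------------------------------------------

def _random_codes(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    draws = rng.choice(4, size=n, p=probs)
    return np.frombuffer("ACGT".encode(), dtype=np.uint8)[draws].copy()


def _scrub_motif(codes: np.ndarray, motif: str, rng: np.random.Generator) -> None:
    """Destroy every motif occurrence in place by mutating its centre base."""
    seq = _decode(codes)
    while True:
        pos = seq.find(motif)
        if pos == -1:
            return
        mid = pos + len(motif) // 2
        old = chr(codes[mid])
        new = BASES[(_CODE[old] + int(rng.integers(1, 4))) % 4]
        codes[mid] = ord(new)
        seq = _decode(codes)


def make_synthetic_genome(config: SyntheticGenomeConfig
                          ) -> tuple[dict[str, str], list[RepeatCopy]]:
    """Build a random genome with planted, divergent repeat families.

    Returns the genome (single sequence ``synthetic_1``) and the repeat
    annotation (0-based half-open coordinates of every placed copy).
    """
    rng = np.random.default_rng(config.seed)
    motif = config.motif.upper()
    m_codes = _encode(motif)
    copy_cycle = list(config.family_copy_numbers)

    if config.family_count is not None:
        n_fam = config.family_count
    else:
        mean_copies = float(np.mean(copy_cycle))
        n_fam = int(round(config.genome_length * config.repeat_fraction
                          / (config.template_length * mean_copies)))
    fam_copies = [copy_cycle[i % len(copy_cycle)] for i in range(n_fam)]
    total_repeat_bp = config.template_length * sum(fam_copies)
    if n_fam and total_repeat_bp >= config.genome_length:
        raise PlacementError(
            f"{n_fam} families x {config.template_length} bp x copies do not fit "
            f"in a {config.genome_length} bp genome"
        )
    if config.template_length < 2 * len(motif) + 2 and n_fam:
        raise PlacementError("template_length too short to carry the motif")

    bg_len = config.genome_length - total_repeat_bp
    background = _random_codes(bg_len, config.gc_content, rng)
    if config.motif_free_background:
        _scrub_motif(background, motif, rng)
        if config.planted_unique_sites:
            u = config.planted_unique_sites
            margin = 2 * config.template_length + 100
            if bg_len - 2 * margin < u * (len(motif) + 20):
                raise PlacementError("background too short for planted unique sites")
            step = (bg_len - 2 * margin) // u
            for i in range(u):
                pos = margin + i * step
                background[pos: pos + len(motif)] = m_codes

    # repeat copies: template per family, motif at the centre, per-copy divergence
    copies: list[tuple[int, int, np.ndarray]] = []  # (family_id, copy_number, codes)
    for fam in range(n_fam):
        template = _random_codes(config.template_length, config.gc_content, rng)
        if config.motif_free_background:
            _scrub_motif(template, motif, rng)
        centre = config.template_length // 2 - len(motif) // 2
        template[centre: centre + len(motif)] = m_codes
        for _ in range(fam_copies[fam]):
            cp = template.copy()
            if config.repeat_divergence > 0:
                mask = rng.random(cp.size) < config.repeat_divergence
                # keep the planted motif intact so every copy stays a site
                mask[centre: centre + len(motif)] = False
                idx = np.flatnonzero(mask)
                if idx.size:
                    base_idx = np.array([_CODE[chr(c)] for c in cp[idx]])
                    alt = (base_idx + rng.integers(1, 4, size=idx.size)) % 4
                    cp[idx] = np.frombuffer("ACGT".encode(), dtype=np.uint8)[alt]
            copies.append((fam + 1, fam_copies[fam], cp))

    order = rng.permutation(len(copies))
    cuts = np.sort(rng.integers(0, bg_len + 1, size=len(copies)))
    pieces: list[np.ndarray] = []
    annotation: list[RepeatCopy] = []
    prev = 0
    pos = 0
    copy_counter: dict[int, int] = {}
    for cut, oi in zip(cuts, order):
        pieces.append(background[prev:cut])
        pos += cut - prev
        fam_id, cn, cp = copies[oi]
        ci = copy_counter.get(fam_id, 0)
        copy_counter[fam_id] = ci + 1
        annotation.append(RepeatCopy("synthetic_1", pos, pos + cp.size, fam_id, ci, cn))
        pieces.append(cp)
        pos += cp.size
        prev = cut
    pieces.append(background[prev:])
    genome_codes = np.concatenate(pieces) if pieces else background
    annotation.sort(key=lambda c: c.start)
    return {"synthetic_1": _decode(genome_codes)}, annotation


def write_repeat_bed(annotation: Sequence[RepeatCopy], path: str | Path) -> None:
    """Write the repeat annotation as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for cp in annotation:
            fh.write(f"{cp.chrom}\t{cp.start}\t{cp.end}\t"
                     f"family{cp.family_id}.copy{cp.copy_index}\t{cp.copy_number}\t+\n")


def simulate_reads(genome: dict[str, str], config: SimConfig,
                   annotation: Sequence[RepeatCopy] = (),
                   rng: np.random.Generator | None = None
                   ) -> tuple[list[ReadRecord], TruthTable]:
    """Full simulation: sites -> tags -> diploidization -> reads.

    Convenience wrapper used by the pipeline and the CLI; fully reproducible
    from ``config.seed`` when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites = find_restriction_sites(genome, config.enzyme_motif)
    tags = extract_tags(genome, sites, config.read_length, annotation,
                        both_flanks=config.both_flanks,
                        motif_length=len(config.enzyme_motif))
    loci, truth = diploidize(tags, config.snp_rate, rng)
    reads = sample_reads(loci, config, rng)
    return reads, truth
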