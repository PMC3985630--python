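"""Genomes and methyltransferase recognition-site maps.

A methyltransferase recognizes a short duplex sequence (e.g. M.TaqI:
5'-TCGA-3', which is its own reverse complement, so one duplex site is one
forward-strand occurrence).  M.FokI is a special case: its two domains
recognize GGATG and CATCC, mutual reverse complements, so a duplex site is a
forward-strand occurrence of either string.  "Star" sites differ from the
canonical recognition sequence by exactly one base and are modified at a
reduced rate; they can be included in a reference map on request.

Coordinates are 0-based, half-open (BED convention) throughout; the reported
position of a duplex site is the forward-strand start of the motif
occurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "RecognitionMotif",
    "SiteRecord",
    "SiteMap",
    "ENZYMES",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "star_variants",
    "random_genome",
    "synthetic_genome_with_sites",
    "find_sites",
    "write_sitemap_bed",
    "read_sitemap_bed",
]

_NUCLEOTIDES = set("ACGT")
# IUPAC degenerate codes are accepted on input but only N is retained as
# "never matches"; anything outside this set is rejected.
_IUPAC = set("ACGTNRYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeSequence:
    """An identified nucleotide sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ValueError(
                f"genome {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RecognitionMotif:
    """A methyltransferase recognition sequence (one or two duplex strings).

    ``motifs`` holds the forward-strand string(s) that define a duplex site:
    a single self-reverse-complementary string (M.TaqI TCGA, M.XbaI TCTAGA)
    or a reverse-complement pair (M.FokI GGATG/CATCC).  ``target_offset``
    gives, per motif string, the 0-based index of the adenine targeted for
    methylation; it is metadata and does not move the mapped site position.
    """

    enzyme_name: str
    motifs: tuple[str, ...]
    target_offset: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("motif list is empty")
        for m in self.motifs:
            if not m or set(m) - _NUCLEOTIDES:
                raise ValueError(f"invalid motif string {m!r}")
        if len(self.motifs) != len(self.target_offset):
            raise ValueError("one target offset per motif string required")
        if len(self.motifs) == 2:
            if reverse_complement(self.motifs[0]) != self.motifs[1]:
                raise ValueError(
                    "a two-string motif must be a reverse-complement pair"
                )

    @property
    def palindromic(self) -> bool:
        return len(self.motifs) == 1 and (
            reverse_complement(self.motifs[0]) == self.motifs[0]
        )

    @property
    def length(self) -> int:
        return len(self.motifs[0])


#: Enzyme presets.  Offsets mark the methylated adenine: TCG[A], TCTAG[A],
#: GG[A]TG and C[A]TCC.
ENZYMES: dict[str, RecognitionMotif] = {
    "M.TaqI": RecognitionMotif("M.TaqI", ("TCGA",), (3,)),
    "M.XbaI": RecognitionMotif("M.XbaI", ("TCTAGA",), (5,)),
    "M.FokI": RecognitionMotif("M.FokI", ("GGATG", "CATCC"), (2, 1)),
}


@dataclass(frozen=True)
class SiteRecord:
    """One duplex recognition site on the genome."""

    start: int  # forward-strand start of the motif occurrence, 0-based
    strand: str  # '+' or '-'
    kind: str  # 'canonical' or 'star'
    mismatches: int  # Hamming distance to the canonical motif

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind not in ("canonical", "star"):
            raise ValueError(f"bad kind {self.kind!r}")
        if (self.mismatches == 0) != (self.kind == "canonical"):
            raise ValueError("mismatches must be 0 iff kind is canonical")


@dataclass
class SiteMap:
    """Ordered reference map of duplex sites for one enzyme on one genome."""

    genome_id: str
    enzyme_name: str
    motif_length: int
    genome_length: int
    records: list[SiteRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.start, r.strand))
        keys = [(r.start, r.strand) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (start, strand) site records")

    @property
    def n_sites(self) -> int:
        return len(self.records)

    def positions(self, kinds: Iterable[str] = ("canonical", "star")) -> list[int]:
        """Forward-strand start positions of sites of the given kinds, sorted."""
        want = set(kinds)
        return [r.start for r in self.records if r.kind in want]


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into GenomeSequence objects.

    Sequences are uppercased; order is preserved.  Empty records or
    non-IUPAC characters raise ValueError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes.append(GenomeSequence(id=rec.id, sequence=str(rec.seq)))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(genomes: Sequence[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


def random_genome(
    length: int, seed: int = 0, genome_id: str = "synthetic", gc: float = 0.5
) -> GenomeSequence:
    """Uniform-composition random genome (synthetic desk-test input)."""
    import numpy as np

    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(int(seed) % 2**31)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return GenomeSequence(id=genome_id, sequence=seq)


def synthetic_genome_with_sites(
    length: int,
    motif: RecognitionMotif,
    n_sites: int,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> GenomeSequence:
    """Random genome carrying exactly ``n_sites`` duplex sites of ``motif``.

    Used to emulate a real genome's map density (e.g. 111 M.TaqI sites on
    the ~40 kb T7 genome): a random background is scrubbed of spontaneous
    motif occurrences, then the motif is planted at uniformly drawn,
    non-overlapping positions and the result re-scanned to confirm the
    exact count.
    """
    import numpy as np

    rng = np.random.default_rng(int(seed) % 2**31)
    mlen = motif.length
    if n_sites < 0 or n_sites * 2 * mlen > length:
        raise ValueError("n_sites does not fit in the genome length")
    words = set(motif.motifs) | {reverse_complement(m) for m in motif.motifs}
    bases = np.array(list("ACGT"))

    for _ in range(50):  # retry if planting creates junction artefacts
        seq = list(rng.choice(bases, size=length))
        # scrub spontaneous occurrences by mutating the occurrence centre
        for _ in range(100):
            text = "".join(seq)
            hits = [p for w in words for p in _forward_occurrences(text, w)]
            if not hits:
                break
            for p in hits:
                j = p + mlen // 2
                seq[j] = rng.choice([b for b in "ACGT" if b != seq[j]])
        starts = []
        for _ in range(10_000):
            if len(starts) == n_sites:
                break
            cand = int(rng.integers(0, length - mlen + 1))
            if all(abs(cand - s) >= 2 * mlen for s in starts):
                starts.append(cand)
        if len(starts) < n_sites:
            continue
        word_choices = sorted(words)
        for s in starts:
            w = word_choices[int(rng.integers(len(word_choices)))]
            seq[s : s + mlen] = list(w)
        genome = GenomeSequence(id=genome_id, sequence="".join(seq))
        if find_sites(genome, motif).n_sites == n_sites:
            return genome
    raise RuntimeError("could not construct a genome with the exact site count")


def star_variants(motif: str) -> set[str]:
    """All sequences at Hamming distance exactly 1 from ``motif``.

    A motif of length L has 3L variants; the canonical sequence itself is
    excluded.
    """
    if not motif:
        raise ValueError("empty motif")
    if set(motif) - _NUCLEOTIDES:
        raise ValueError(f"motif {motif!r} not over ACGT")
    out = set()
    for i, base in enumerate(motif):
        for sub in _NUCLEOTIDES - {base}:
            out.add(motif[:i] + sub + motif[i + 1 :])
    return out


def _forward_occurrences(sequence: str, word: str) -> list[int]:
    """All (overlapping) exact forward-strand occurrences of ``word``.

    N in the genome never matches.
    """
    hits = []
    start = sequence.find(word)
    while start != -1:
        hits.append(start)
        start = sequence.find(word, start + 1)
    return hits


def find_sites(
    genome: GenomeSequence,
    motif: RecognitionMotif,
    include_star: bool = False,
) -> SiteMap:
    """Scan a genome for duplex recognition sites of one enzyme.

    The duplex site set is defined by forward-strand occurrences of the
    motif string(s): a self-reverse-complementary motif is found on both
    strands by a single forward scan, and for a reverse-complement pair
    (GGATG/CATCC) a forward occurrence of either string is one duplex site.
    Overlapping occurrences are all reported.  With ``include_star``,
    Hamming-distance-1 variants of every motif string are scanned too; for
    these same duplex closure argument applies (the reverse complement of a
    variant of one string is a variant of the paired string), so a forward
    scan over all variants covers both strands.
    """
    if motif.length > genome.length:
        warnings.warn(
            f"motif {motif.enzyme_name} longer than genome {genome.id}; empty map"
        )
        return SiteMap(genome.id, motif.enzyme_name, motif.length, genome.length)

    records: dict[tuple[int, str], SiteRecord] = {}

    def add(start: int, strand: str, kind: str, mism: int) -> None:
        key = (start, strand)
        # canonical wins over star at the same locus; first writer otherwise
        if key in records and records[key].kind == "canonical":
            return
        records[key] = SiteRecord(start, strand, kind, mism)

    if len(motif.motifs) == 2:
        scan = list(zip(motif.motifs, ("+", "-")))
    elif motif.palindromic:
        scan = [(motif.motifs[0], "+")]
    else:
        # single non-palindromic string: its reverse complement marks the
        # same duplex site read from the other strand
        scan = [
            (motif.motifs[0], "+"),
            (reverse_complement(motif.motifs[0]), "-"),
        ]
    for word, strand in scan:
        for start in _forward_occurrences(genome.sequence, word):
            add(start, strand, "canonical", 0)

    if include_star:
        for word, strand in scan:
            for variant in sorted(star_variants(word)):
                for start in _forward_occurrences(genome.sequence, variant):
                    add(start, strand, "star", 1)

    return SiteMap(
        genome.id,
        motif.enzyme_name,
        motif.length,
        genome.length,
        list(records.values()),
    )


def write_sitemap_bed(sitemap: SiteMap, path: str | Path) -> None:
    """Write a site map as BED6: chrom, start, end, enzyme:kind, mismatches, strand."""
    with open(path, "w") as fh:
        fh.write(
            f"#genome_length={sitemap.genome_length}\t"
            f"motif_length={sitemap.motif_length}\n"
        )
        for r in sitemap.records:
            fh.write(
                f"{sitemap.genome_id}\t{r.start}\t{r.start + sitemap.motif_length}\t"
                f"{sitemap.enzyme_name}:{r.kind}\t{r.mismatches}\t{r.strand}\n"
            )


def read_sitemap_bed(path: str | Path) -> SiteMap:
    """Read a site map written by :func:`write_sitemap_bed`."""
    genome_id = enzyme = None
    genome_length = motif_length = None
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                meta = dict(f.split("=", 1) for f in line[1:].split("\t"))
                genome_length = int(meta["genome_length"])
                motif_length = int(meta["motif_length"])
                continue
            chrom, start, end, name, score, strand = line.split("\t")
            genome_id = chrom
            enzyme, kind = name.rsplit(":", 1)
            records.append(SiteRecord(int(start), strand, kind, int(score)))
    if genome_length is None or motif_length is None:
        raise ValueError(f"{path}: missing metadata header line")
    if not records:
        raise ValueError(f"{path}: no site records")
    return SiteMap(genome_id, enzyme, motif_length, genome_length, records)
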