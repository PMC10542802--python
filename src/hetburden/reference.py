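"""Packaged mtDNA gene map and substitution-consequence annotation.

The mitochondrial genome is a 16,569-bp circle annotated with 13 protein
genes (grouped by OXPHOS complex), 22 tRNAs, 2 rRNAs, the control region
(D-loop, wrapping m.16024-m.576) and 87 intergenic spacer bases.  Protein
consequences are evaluated under the vertebrate mitochondrial genetic code
(translation table 2: AGA/AGG are stops, ATA is Met, TGA is Trp), with
light-strand genes read on the reverse complement.

The packaged reference sequence is a synthetic stand-in for the rCRS: a
seeded random sequence constrained so that every protein gene is a clean
open reading frame and the documented example substitutions (m.3308 T>G,
m.15327 C>G) create stop codons, as they do on the real genome.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from Bio.Data import CodonTable

GENOME_LENGTH = 16_569

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
STOP_CODONS = frozenset(_MITO_TABLE.stop_codons)          # TAA TAG AGA AGG
START_CODONS = frozenset({"ATG", "ATA", "ATT", "GTG"})
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: consequence kinds ordered most to least severe (protein kinds only)
SEVERITY = ("stop_gained", "start_lost", "stop_lost", "missense", "synonymous")


def translate_codon(codon: str) -> str:
    """Amino acid (one letter) for ``codon`` under table 2; '*' for stops."""
    if codon in STOP_CODONS:
        return "*"
    return _MITO_TABLE.forward_table[codon]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature, 1-based inclusive coordinates.

    The control region wraps the origin (start 16024 > end 576); every
    other feature has ``start <= end``.
    """

    name: str
    start: int
    end: int
    strand: str            # "H" (heavy) or "L" (light)
    product_class: str     # protein | tRNA | rRNA | noncoding
    complex: str           # ComplexI/III/IV/V or "none"

    def positions(self) -> range | list[int]:
        if self.start <= self.end:
            return range(self.start, self.end + 1)
        # wrapping feature (control region)
        return list(range(self.start, GENOME_LENGTH + 1)) + list(range(1, self.end + 1))

    def __len__(self) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return (GENOME_LENGTH - self.start + 1) + self.end

    def contains(self, pos: int) -> bool:
        if self.start <= self.end:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end


@dataclass(frozen=True)
class Consequence:
    """Functional consequence of one substitution.

    ``kind`` is one of synonymous / missense / stop_gained / start_lost /
    stop_lost for protein positions, else tRNA / rRNA / noncoding.
    ``codon_change`` is "REF>ALT" on the coding strand for protein kinds.
    ``incomplete_stop`` flags substitutions in the 1-2 trailing bases of
    genes whose stop codon is completed by polyadenylation; they are
    annotated by the completed-codon (appended A) convention.
    """

    kind: str
    gene: str | None = None
    codon_change: str | None = None
    incomplete_stop: bool = False

    @property
    def is_protein(self) -> bool:
        return self.kind in SEVERITY

    @property
    def is_nonsynonymous(self) -> bool:
        return self.kind in ("missense", "stop_gained", "start_lost", "stop_lost")


# Region labels used for the eight-way genome partition.
REGION_LABELS = (
    "ComplexI", "ComplexIII", "ComplexIV", "ComplexV",
    "D-loop", "tRNA", "rRNA", "unassigned",
)


class GeneMap:
    """The packaged annotation plus reference sequence.

    ``classify_region`` assigns every position exactly one of the eight
    region labels; overlapping genes (MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4,
    MT-TI/MT-TQ, MT-TC/MT-TY) always share a label, so the labelling is a
    strict partition whose per-label counts reproduce the published
    region lengths (Complex I 6349 ... unassigned 87; total 16,569).
    """

    def __init__(self, features: list[GeneFeature], sequence: str):
        if len(sequence) != GENOME_LENGTH:
            raise ValueError(
                f"reference sequence must be {GENOME_LENGTH} bp, got {len(sequence)}"
            )
        bad = set(sequence) - set("ACGT")
        if bad:
            raise ValueError(f"reference sequence contains non-ACGT bases: {sorted(bad)}")
        self.features = list(features)
        self.sequence = sequence
        self.genome_length = GENOME_LENGTH
        self._region = self._build_region_index()

    # -- construction helpers -------------------------------------------------

    def _build_region_index(self) -> list[str]:
        region = ["unassigned"] * (GENOME_LENGTH + 1)  # 1-based
        for feat in self.features:
            if feat.product_class == "protein":
                label = feat.complex
            elif feat.product_class in ("tRNA", "rRNA"):
                label = feat.product_class
            else:
                label = "D-loop"
            for pos in feat.positions():
                prev = region[pos]
                if prev != "unassigned" and prev != label:
                    raise ValueError(
                        f"position {pos} assigned to both {prev} and {label}; "
                        "the annotation must partition the genome"
                    )
                region[pos] = label
        return region

    # -- queries --------------------------------------------------------------

    def base(self, pos: int) -> str:
        self._check_pos(pos)
        return self.sequence[pos - 1]

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= GENOME_LENGTH:
            raise ValueError(f"position {pos} outside 1..{GENOME_LENGTH}")

    def features_at(self, pos: int) -> list[GeneFeature]:
        self._check_pos(pos)
        return [f for f in self.features if f.contains(pos)]

    def classify_region(self, pos: int) -> str:
        self._check_pos(pos)
        return self._region[pos]

    def region_lengths(self) -> dict[str, int]:
        counts = {label: 0 for label in REGION_LABELS}
        for pos in range(1, GENOME_LENGTH + 1):
            counts[self._region[pos]] += 1
        return counts

    def protein_positions(self) -> set[int]:
        """All positions inside at least one protein gene."""
        out: set[int] = set()
        for f in self.features:
            if f.product_class == "protein":
                out.update(f.positions())
        return out

    # -- consequence annotation ----------------------------------------------

    def coding_sequence(self, feat: GeneFeature) -> str:
        """Coding-strand sequence of a protein gene (5'->3' of its mRNA)."""
        raw = self.sequence[feat.start - 1:feat.end]
        return reverse_complement(raw) if feat.strand == "L" else raw

    def _protein_consequence(self, feat: GeneFeature, pos: int, alt: str) -> Consequence:
        cds = self.coding_sequence(feat)
        if feat.strand == "H":
            offset = pos - feat.start
            alt_base = alt
        else:
            offset = feat.end - pos
            alt_base = alt.translate(_COMPLEMENT)
        codon_idx, in_codon = divmod(offset, 3)
        n_full = len(cds) // 3
        trailing = len(cds) % 3

        if codon_idx >= n_full:  # 1-2 trailing bases: polyA-completed stop
            tail = cds[n_full * 3:]
            ref_codon = (tail + "AA")[:3]
            alt_tail = tail[:in_codon] + alt_base + tail[in_codon + 1:]
            alt_codon = (alt_tail + "AA")[:3]
            incomplete = True
        else:
            ref_codon = cds[codon_idx * 3:codon_idx * 3 + 3]
            alt_codon = ref_codon[:in_codon] + alt_base + ref_codon[in_codon + 1:]
            incomplete = False

        change = f"{ref_codon}>{alt_codon}"
        if alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
            kind = "stop_gained"
        elif codon_idx == 0 and ref_codon in START_CODONS and alt_codon not in START_CODONS:
            kind = "start_lost"
        elif ref_codon in STOP_CODONS and alt_codon not in STOP_CODONS:
            kind = "stop_lost"
        elif translate_codon(ref_codon) == translate_codon(alt_codon):
            kind = "synonymous"
        else:
            kind = "missense"
        return Consequence(kind, feat.name, change, incomplete)

    def annotate_substitution(self, pos: int, ref: str, alt: str) -> Consequence:
        """Consequence of a single-base substitution.

        For positions inside two protein genes the most severe
        consequence across reading frames is reported (stop_gained >
        start/stop_lost > missense > synonymous).
        """
        self._check_pos(pos)
        for b, label in ((ref, "ref"), (alt, "alt")):
            if b not in "ACGT" or len(b) != 1:
                raise ValueError(f"{label} allele {b!r} is not one of A,C,G,T")
        if ref == alt:
            raise ValueError("alt allele equals ref allele")
        expected = self.base(pos)
        if ref != expected:
            raise ValueError(
                f"ref allele {ref} does not match reference base {expected} at m.{pos}"
            )

        protein = [f for f in self.features_at(pos) if f.product_class == "protein"]
        if protein:
            results = [self._protein_consequence(f, pos, alt) for f in protein]
            return min(results, key=lambda c: SEVERITY.index(c.kind))

        region = self.classify_region(pos)
        if region in ("tRNA", "rRNA"):
            return Consequence(region)
        return Consequence("noncoding")


# -- packaged fixture ---------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("hetburden").joinpath("data", name)


def read_gene_table(path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["name", "start", "end", "strand", "product_class", "complex"]:
            raise ValueError(f"unexpected gene-table header in {path}: {header}")
        for line in fh:
            name, start, end, strand, pclass, cplx = line.rstrip("\n").split("\t")
            feats.append(GeneFeature(name, int(start), int(end), strand, pclass, cplx))
    return feats


def read_fasta_sequence(path) -> str:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise ValueError(f"{path} is not FASTA: missing '>' header")
        return "".join(line.strip() for line in fh)


# published per-region unique-base lengths; validated on every load
EXPECTED_REGION_LENGTHS = {
    "ComplexI": 6349,
    "ComplexIII": 1141,
    "ComplexIV": 3010,
    "ComplexV": 842,
    "D-loop": 1122,
    "tRNA": 1505,
    "rRNA": 2513,
    "unassigned": 87,
}


def load_gene_map() -> GeneMap:
    """Load and validate the packaged annotation and synthetic sequence."""
    table_path = _data_path("gene_map.tsv")
    fasta_path = _data_path("mtdna_synthetic.fasta")
    try:
        feats = read_gene_table(table_path)
        seq = read_fasta_sequence(fasta_path)
        gmap = GeneMap(feats, seq)
    except Exception as exc:  # identify the corrupt fixture explicitly
        raise RuntimeError(
            f"corrupt packaged reference fixture ({table_path}, {fasta_path}): {exc}"
        ) from exc
    lengths = gmap.region_lengths()
    if lengths != EXPECTED_REGION_LENGTHS:
        raise RuntimeError(
            f"packaged gene map region lengths {lengths} do not match the "
            f"expected partition {EXPECTED_REGION_LENGTHS} ({table_path})"
        )
    return gmap


def classify_region(gmap: GeneMap, pos: int) -> str:
    """Module-level convenience wrapper around :meth:`GeneMap.classify_region`."""
    return gmap.classify_region(pos)


def annotate_substitution(gmap: GeneMap, pos: int, ref: str, alt: str) -> Consequence:
    """Module-level convenience wrapper around :meth:`GeneMap.annotate_substitution`."""
    return gmap.annotate_substitution(pos, ref, alt)
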