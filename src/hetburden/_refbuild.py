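"""Builder for the packaged synthetic mtDNA reference fixture.

The gene coordinates follow the public mitochondrial gene structure with
three 1-bp boundary adjustments at ambiguous junctions so that the
eight-way region partition (by OXPHOS complex / gene type) reproduces the
published unique-base tallies exactly.  The sequence itself is synthetic:
a seeded random sequence overwritten gene-by-gene so that every protein
gene is a valid open reading frame under the vertebrate mitochondrial
code, including the two documented stop-gain examples:

* MT-ND1 starts ATA, so m.3308 T>G gives ATA>AGA (stop gained);
* MT-CYB codon 194 is ACA, so m.15327 C>G gives ACA>AGA (stop gained).

Genes whose length is not a codon multiple end in 1-2 trailing bases
("T"/"TA") completed to TAA by polyadenylation, mirroring the real genome.
"""

from __future__ import annotations

import numpy as np

from .reference import (
    GENOME_LENGTH,
    GeneFeature,
    GeneMap,
    STOP_CODONS,
    reverse_complement,
)

BUILD_SEED = 173_205_080  # fixed: the fixture is a deterministic artifact

GENE_TABLE: list[tuple[str, int, int, str, str, str]] = [
    ("MT-DLOOP", 16024, 576, "H", "noncoding", "none"),
    ("MT-TF", 577, 647, "H", "tRNA", "none"),
    ("MT-RNR1", 648, 1601, "H", "rRNA", "none"),
    ("MT-TV", 1602, 1670, "H", "tRNA", "none"),
    ("MT-RNR2", 1671, 3229, "H", "rRNA", "none"),
    ("MT-TL1", 3230, 3304, "H", "tRNA", "none"),
    ("MT-ND1", 3307, 4262, "H", "protein", "ComplexI"),
    ("MT-TI", 4263, 4331, "H", "tRNA", "none"),
    ("MT-TQ", 4329, 4400, "L", "tRNA", "none"),
    ("MT-TM", 4402, 4469, "H", "tRNA", "none"),
    ("MT-ND2", 4470, 5511, "H", "protein", "ComplexI"),
    ("MT-TW", 5512, 5579, "H", "tRNA", "none"),
    ("MT-TA", 5587, 5655, "L", "tRNA", "none"),
    ("MT-TN", 5657, 5729, "L", "tRNA", "none"),
    ("MT-TC", 5761, 5826, "L", "tRNA", "none"),
    ("MT-TY", 5826, 5891, "L", "tRNA", "none"),
    ("MT-CO1", 5904, 7445, "H", "protein", "ComplexIV"),
    ("MT-TS1", 7446, 7514, "L", "tRNA", "none"),
    ("MT-TD", 7518, 7585, "H", "tRNA", "none"),
    ("MT-CO2", 7586, 8270, "H", "protein", "ComplexIV"),
    ("MT-TK", 8295, 8365, "H", "tRNA", "none"),
    ("MT-ATP8", 8366, 8572, "H", "protein", "ComplexV"),
    ("MT-ATP6", 8527, 9207, "H", "protein", "ComplexV"),
    ("MT-CO3", 9208, 9990, "H", "protein", "ComplexIV"),
    ("MT-TG", 9991, 10058, "H", "tRNA", "none"),
    ("MT-ND3", 10059, 10404, "H", "protein", "ComplexI"),
    ("MT-TR", 10405, 10469, "H", "tRNA", "none"),
    ("MT-ND4L", 10470, 10766, "H", "protein", "ComplexI"),
    ("MT-ND4", 10760, 12137, "H", "protein", "ComplexI"),
    ("MT-TH", 12138, 12206, "H", "tRNA", "none"),
    ("MT-TS2", 12207, 12265, "H", "tRNA", "none"),
    ("MT-TL2", 12266, 12336, "H", "tRNA", "none"),
    ("MT-ND5", 12337, 14148, "H", "protein", "ComplexI"),
    ("MT-ND6", 14149, 14673, "L", "protein", "ComplexI"),
    ("MT-TE", 14674, 14742, "L", "tRNA", "none"),
    ("MT-CYB", 14747, 15887, "H", "protein", "ComplexIII"),
    ("MT-TT", 15888, 15953, "H", "tRNA", "none"),
    ("MT-TP", 15956, 16023, "L", "tRNA", "none"),
]

_BASES = np.array(list("ACGT"))
_NONSTOP = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def build_features() -> list[GeneFeature]:
    return [GeneFeature(*row) for row in GENE_TABLE]


def _random_nonstop(rng) -> str:
    return _NONSTOP[rng.integers(len(_NONSTOP))]


def _write(seq: list[str], pos1: int, fragment: str) -> None:
    """Write ``fragment`` starting at 1-based position ``pos1``."""
    seq[pos1 - 1:pos1 - 1 + len(fragment)] = list(fragment)


def _heavy_cds(length: int, rng, pinned: dict[int, str] | None = None,
               start_codon: str = "ATG", stop_end: bool = True) -> str:
    """Random clean ORF of ``length`` bases on the coding strand.

    ``stop_end=False`` builds an ORF prefix (used for the 5' part of a
    gene whose tail is dictated by an overlapping downstream gene).
    """
    pinned = pinned or {}
    n_full, trailing = divmod(length, 3)
    codons = []
    for i in range(n_full):
        if i in pinned:
            codons.append(pinned[i])
        elif i == 0:
            codons.append(start_codon)
        elif i == n_full - 1 and trailing == 0 and stop_end:
            codons.append("TAA")
        else:
            codons.append(_random_nonstop(rng))
    tail = {0: "", 1: "T", 2: "TA"}[trailing]
    return "".join(codons) + tail


def _frame_codons(seq: list[str], start: int, length: int) -> list[str]:
    cds = "".join(seq[start - 1:start - 1 + length])
    return [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]


def build_sequence(seed: int = BUILD_SEED) -> str:
    rng = np.random.default_rng(seed)
    seq = list(_BASES[rng.integers(4, size=GENOME_LENGTH)])

    # simple heavy-strand genes
    _write(seq, 3307, _heavy_cds(956, rng, pinned={0: "ATA", 2: "ATA"},
                                 start_codon="ATA"))          # MT-ND1
    _write(seq, 4470, _heavy_cds(1042, rng))                   # MT-ND2
    _write(seq, 5904, _heavy_cds(1542, rng))                   # MT-CO1
    _write(seq, 7586, _heavy_cds(685, rng))                    # MT-CO2
    _write(seq, 9208, _heavy_cds(783, rng))                    # MT-CO3
    _write(seq, 10059, _heavy_cds(346, rng))                   # MT-ND3
    _write(seq, 12337, _heavy_cds(1812, rng))                  # MT-ND5
    _write(seq, 14747, _heavy_cds(1141, rng, pinned={193: "ACA"}))  # MT-CYB

    # MT-ND6 is on the light strand: build its mRNA, store the complement
    nd6 = _heavy_cds(525, rng)
    _write(seq, 14149, reverse_complement(nd6))

    # MT-ATP6 (8527-9207) overlaps MT-ATP8 (8366-8572) in a shifted frame.
    # Codons 14/15 are pinned so ATP8's final codon (8570-8572) reads TAA;
    # the free overlap codons are resampled until ATP8's frame is stop-free.
    for _ in range(1000):
        atp6 = _heavy_cds(681, rng, pinned={14: "CTA", 15: "ACA"})
        _write(seq, 8527, atp6)
        # ATP8 bases 8528..8569 fall in codons 54..67 of ATP8's frame
        overlap = _frame_codons(seq, 8528, 42)
        if not any(c in STOP_CODONS for c in overlap):
            break
    else:  # pragma: no cover - probability of exhausting retries ~ 0
        raise RuntimeError("could not satisfy ATP8/ATP6 overlap constraints")

    # MT-ATP8 free part: codons 0..52 at 8366..8524, then codon 53 whose
    # third base is ATP6's fixed 'A' at 8527
    _write(seq, 8366, _heavy_cds(159, rng, stop_end=False))
    while True:
        pair = _random_nonstop(rng)[:2]
        if pair not in ("TA", "AG"):               # pair + 'A' must not be a stop
            break
    _write(seq, 8525, pair)

    # MT-ND4 (10760-12137) overlaps MT-ND4L (10470-10766) in a shifted
    # frame; pinned first codons make ND4L's final codon (10764-10766) TAA.
    _write(seq, 10760, _heavy_cds(1378, rng, pinned={0: "ATG", 1: "CTA", 2: "ACC"}))
    # MT-ND4L free part: codons 0..95 at 10470..10757, then two free bases
    # of codon 96 whose third base is ND4's fixed 'A' at 10760
    _write(seq, 10470, _heavy_cds(288, rng, stop_end=False))
    while True:
        pair = _random_nonstop(rng)[:2]
        if pair not in ("TA", "AG"):
            break
    _write(seq, 10758, pair)

    sequence = "".join(seq)
    _verify_orfs(sequence)
    return sequence


def _verify_orfs(sequence: str) -> None:
    """Assert every protein gene translates cleanly; guards the fixture."""
    gmap = GeneMap(build_features(), sequence)
    from .reference import START_CODONS, translate_codon

    for feat in gmap.features:
        if feat.product_class != "protein":
            continue
        cds = gmap.coding_sequence(feat)
        n_full, trailing = divmod(len(cds), 3)
        codons = [cds[i * 3:i * 3 + 3] for i in range(n_full)]
        assert codons[0] in START_CODONS, f"{feat.name}: bad start {codons[0]}"
        body = codons[1:-1] if trailing == 0 else codons[1:]
        assert not any(c in STOP_CODONS for c in body), f"{feat.name}: internal stop"
        if trailing == 0:
            assert codons[-1] in STOP_CODONS, f"{feat.name}: missing stop"
        else:
            completed = (cds[n_full * 3:] + "AA")[:3]
            assert completed in STOP_CODONS, f"{feat.name}: bad incomplete stop"
        for codon in body:
            translate_codon(codon)  # raises on anything untranslatable


def build_gene_map(seed: int = BUILD_SEED) -> GeneMap:
    return GeneMap(build_features(), build_sequence(seed))


def write_fixture(data_dir) -> None:
    """Write gene_map.tsv and mtdna_synthetic.fasta into ``data_dir``."""
    import pathlib

    data_dir = pathlib.Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    with open(data_dir / "gene_map.tsv", "w") as fh:
        fh.write("name\tstart\tend\tstrand\tproduct_class\tcomplex\n")
        for row in GENE_TABLE:
            fh.write("\t".join(str(x) for x in row) + "\n")
    seq = build_sequence()
    with open(data_dir / "mtdna_synthetic.fasta", "w") as fh:
        fh.write(">chrM synthetic mtDNA reference stand-in (16569 bp)\n")
        for i in range(0, GENOME_LENGTH, 70):
            fh.write(seq[i:i + 70] + "\n")
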