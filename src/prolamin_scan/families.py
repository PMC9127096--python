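"""Synthetic sequence templates for oat seed storage-protein families.

Everything here is a synthetic stand-in built to reproduce the *structural*
facts of the real gene families, not their actual sequences:

* avenins: 19-residue signal peptide, three conserved domains, two
  proline/glutamine/leucine-rich repetitive domains and a C-terminal domain;
  eight cysteines (nine in group A, the ninth in the C-terminal domain);
  one family-specific celiac T-cell epitope per protein, and for group C2 a
  tandem block of the 9-mer PFVQQQQPF in the first repetitive domain;
* globulins: signal peptide + four exons interrupted by three short introns
  (in the genomic copy only) + variable C-terminal region;
* alpha-amylase/trypsin inhibitors (AATI): leader peptide + mature chain,
  four families (1, 2, 3 and an unclassified group).

Gene starts are compatible with the degenerate enrichment probes so the
generator's transcripts carry the probe binding motifs.  Distinct genomic
copies of the same family receive sparse synonymous codon swaps so that
long reads can be assigned to their locus of origin; the exemplar used for
classification is the swap-free base sequence.
"""

from __future__ import annotations

import zlib

import numpy as np

from .io_core import DegenerateMotif, degenerate_match, translate

# ---------------------------------------------------------------------------
# Codon usage (fixed primary codon per amino acid + one synonymous alternate)
# ---------------------------------------------------------------------------

CODON: dict[str, str] = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGC",
    "E": "GAA", "Q": "CAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTC", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAC", "V": "GTT",
}

CODON_ALT: dict[str, str] = {
    "A": "GCA", "R": "CGA", "N": "AAC", "D": "GAC", "C": "TGT",
    "E": "GAG", "Q": "CAG", "G": "GGA", "H": "CAC", "I": "ATC",
    "L": "CTA", "K": "AAG", "F": "TTT", "P": "CCT", "S": "TCA",
    "T": "ACA", "Y": "TAT", "V": "GTA",
}

STOP_CODON = "TAA"

#: codon classes are spaced this many codons apart for per-copy swaps
_SWAP_PERIOD = 23


def reverse_translate(protein: str, copy_index: int | None = None,
                      override: tuple[str, ...] = ()) -> str:
    """Deterministic reverse translation (no stop appended).

    ``override`` fixes the first codons (must be synonymous with the protein).
    ``copy_index`` applies sparse synonymous swaps (one codon class per copy)
    so sibling gene copies are distinguishable at the nucleotide level.
    """
    codons: list[str] = []
    for j, aa in enumerate(protein):
        if j < len(override):
            cod = override[j]
            if translate(cod) != aa:
                raise ValueError(f"override codon {cod} does not encode {aa}")
        else:
            cod = CODON[aa]
            if (copy_index is not None and aa in CODON_ALT
                    and j % _SWAP_PERIOD == (7 * copy_index) % _SWAP_PERIOD):
                cod = CODON_ALT[aa]
        codons.append(cod)
    return "".join(codons)


def _diverge(seq: str, tag: str, rate: float, alphabet: str,
             protect: str = "C") -> str:
    """Deterministically mutate ``seq`` at ~rate, sparing protected residues."""
    rng = np.random.RandomState(zlib.crc32(tag.encode()) % (2**31))
    out = []
    for aa in seq:
        if aa not in protect and rng.random_sample() < rate:
            choices = [c for c in alphabet if c != aa]
            out.append(choices[rng.randint(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _random_protein(tag: str, length: int, alphabet: str = "AVTSGNDEFYHRKMIWC") -> str:
    rng = np.random.RandomState(zlib.crc32(tag.encode()) % (2**31))
    return "".join(alphabet[rng.randint(len(alphabet))] for _ in range(length))


# ---------------------------------------------------------------------------
# Enrichment probes (degenerate, IUPAC); the 5' vector part is omitted
# ---------------------------------------------------------------------------

AVENIN_PROBE_TAIL = DegenerateMotif("ATGARGAMCTTYCTCATC")
GLOBULIN_PROBE_TAIL = DegenerateMotif("ATGGYAAYYAYYRGBWTBYSATC")
AATI_PROBE_TAIL = DegenerateMotif("ATGGCGTCC")

PROBE_TAILS: dict[str, DegenerateMotif] = {
    "avenin": AVENIN_PROBE_TAIL,
    "globulin": GLOBULIN_PROBE_TAIL,
    "AATI": AATI_PROBE_TAIL,
}

#: probe-compatible start codons (checked against the signal/leader peptides)
AVENIN_START_CODONS = ("ATG", "AAG", "ACC", "TTC", "CTC", "ATC")
GLOBULIN_START_CODONS = ("ATG", "GCA", "ACC", "ACT", "AGC", "ATT", "TCA", "TCC")
AATI_START_CODONS = ("ATG", "GCG", "TCC")

# ---------------------------------------------------------------------------
# Celiac T-cell epitopes planted per family (HLA-DQ2.5 restricted)
# ---------------------------------------------------------------------------

EPITOPE_AVE_1A = "PYPEQQEPF"      # canonical, group C2
EPITOPE_AVE_1B_VARIANT = "PYPEQQQPF"   # observed oat form of ave-1b, group C1
EPITOPE_AVE_1C_VARIANT = "PYPEQQQPI"   # observed oat form of ave-1c, group B
EPITOPE_AVE_2 = "PYPEQQPF"        # canonical, group A
EPITOPE_GAMMA9B = "PFVQQQQPF"     # tandem 9-mer in C2 first repetitive domain

#: per-protein epitope occurrences planted by the generator, by family
PLANTED_EPITOPES: dict[str, dict[str, int]] = {
    "DQ2.5-ave-1a": {"avenin-C2": 1},
    "DQ2.5-ave-1b": {"avenin-C1": 1},
    "DQ2.5-ave-1c": {"avenin-B": 1},
    "DQ2.5-ave-2": {"avenin-A": 1},
    "Av-gamma9B": {"avenin-C2": None},   # None -> c2_repeat_count copies
}

# ---------------------------------------------------------------------------
# Avenins
# ---------------------------------------------------------------------------

AVENIN_FAMILIES = ("avenin-A", "avenin-B", "avenin-C1", "avenin-C2", "avenin-D")

AVENIN_SIGNAL = "MKTFLILALLAIVATTATA"          # 19 aa; starts M K T F L I
_AVENIN_CONS1 = "TTVEDNARSIAGVGE"              # 15 aa, no C/P/Q/L
_AVENIN_CONS2 = "SRCDVMNECRAYVAECNIGSTVCEAFRSVD"  # 30 aa, 4 cysteines
_AVENIN_CONS3 = "GVDTRCSYEAMCGNVRSTCDAIVECSHGFA"  # 30 aa, 4 cysteines
_AVENIN_CTERM = "VGTMDNAYHEVARSF"              # 15 aa
_AVENIN_CTERM_A = "VGTMDNACHEVARSF"            # group A: ninth cysteine

#: P/Q/L-rich repeat units of the two variable (repetitive) domains
_REPEAT_UNIT = {
    "avenin-A": "LQPQQQF",
    "avenin-B": "QQPLQQF",
    "avenin-C1": "LQLQPQF",
    "avenin-C2": "QQPQLQF",
    "avenin-D": "PLPLSQF",
}

#: (repetitive1 length, repetitive2 length) in residues
_REPEAT_LENGTHS = {
    "avenin-A": (40, 35),
    "avenin-B": (45, 40),
    "avenin-C1": (50, 45),
    "avenin-C2": (55, 50),
    "avenin-D": (30, 30),
}

_FAMILY_EPITOPE = {
    "avenin-A": EPITOPE_AVE_2,
    "avenin-B": EPITOPE_AVE_1C_VARIANT,
    "avenin-C1": EPITOPE_AVE_1B_VARIANT,
    "avenin-C2": EPITOPE_AVE_1A,
    "avenin-D": "",
}

# divergence alphabet excludes C (cysteine census) and P/Q/L (repeat signal)
_CONS_ALPHABET = "AVTSGNDEFYHRKMIW"
_CONS_DIVERGENCE = {
    "avenin-A": 0.10, "avenin-B": 0.10, "avenin-C1": 0.10,
    "avenin-C2": 0.10, "avenin-D": 0.35,
}

AVENIN_DOMAIN_NAMES = (
    "signal_peptide", "conserved1", "repetitive1", "conserved2",
    "repetitive2", "conserved3", "c_terminal",
)


def _fill(unit: str, length: int) -> str:
    reps = -(-length // len(unit))
    return (unit * reps)[:length]


def avenin_protein(family: str, c2_repeat_count: int = 3
                   ) -> tuple[str, dict[str, tuple[int, int]]]:
    """Avenin protein (incl. signal peptide) and its true domain boundaries."""
    if family not in AVENIN_FAMILIES:
        raise ValueError(f"unknown avenin family {family!r}")
    unit = _REPEAT_UNIT[family]
    len1, len2 = _REPEAT_LENGTHS[family]
    rate = _CONS_DIVERGENCE[family]
    cons1 = _diverge(_AVENIN_CONS1, f"{family}/cons1", rate, _CONS_ALPHABET)
    cons2 = _diverge(_AVENIN_CONS2, f"{family}/cons2", rate, _CONS_ALPHABET)
    cons3 = _diverge(_AVENIN_CONS3, f"{family}/cons3", rate, _CONS_ALPHABET)
    cterm = _AVENIN_CTERM_A if family == "avenin-A" else _AVENIN_CTERM

    if family == "avenin-C2":
        if c2_repeat_count not in (2, 3):
            raise ValueError("c2_repeat_count must be 2 or 3")
        tandem = "PFVQQQQ" * c2_repeat_count + "PF"
        head = _FAMILY_EPITOPE[family] + tandem
        rep1 = head + _fill(unit, len1 - len(head))
    else:
        head = _FAMILY_EPITOPE[family]
        rep1 = head + _fill(unit, len1 - len(head))
    rep2 = _fill(unit, len2)

    parts = [AVENIN_SIGNAL, cons1, rep1, cons2, rep2, cons3, cterm]
    boundaries: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, part in zip(AVENIN_DOMAIN_NAMES, parts):
        boundaries[name] = (pos, pos + len(part))
        pos += len(part)
    return "".join(parts), boundaries


def avenin_cds(family: str, copy_index: int | None = None,
               c2_repeat_count: int = 3) -> str:
    """Avenin coding sequence including the terminal stop codon."""
    protein, _ = avenin_protein(family, c2_repeat_count)
    return reverse_translate(protein, copy_index, AVENIN_START_CODONS) + STOP_CODON


# ---------------------------------------------------------------------------
# Globulins
# ---------------------------------------------------------------------------

GLOBULIN_GROUPS = ("globulin-A", "globulin-B", "globulin-C", "globulin-D")

GLOBULIN_SIGNAL = "MATTSISSVLAVFASA"   # 16 aa; starts M A T T S I S S
_GLOBULIN_MATURE_LEN = 208
_GLOBULIN_MATURE_BASE = _random_protein("globulin/mature", _GLOBULIN_MATURE_LEN)

#: introns are inserted after these codon offsets of the spliced CDS
GLOBULIN_INTRON_CODON_OFFSETS = (66, 114, 158)

# in-frame, stop-free introns (GT...AG), lengths within the observed 104-137 bp
GLOBULIN_INTRONS = (
    "GTA" + "CCA" * 37 + "CAG",   # 117 bp
    "GTA" + "CCT" * 40 + "CAG",   # 126 bp
    "GTA" + "CAT" * 33 + "CAG",   # 105 bp
)


def globulin_protein(group: str) -> str:
    """Spliced globulin protein (signal + mature chain), per group."""
    if group not in GLOBULIN_GROUPS:
        raise ValueError(f"unknown globulin group {group!r}")
    mature = _diverge(_GLOBULIN_MATURE_BASE, f"{group}/mature", 0.30,
                      "AVTSGNDEFYHRKIWQ", protect="")
    return GLOBULIN_SIGNAL + mature


def globulin_spliced_cds(group: str, copy_index: int | None = None) -> str:
    protein = globulin_protein(group)
    return reverse_translate(protein, copy_index, GLOBULIN_START_CODONS) + STOP_CODON


def globulin_genomic_cds(group: str, copy_index: int | None = None
                         ) -> tuple[str, list[tuple[int, int]]]:
    """Genomic globulin copy with introns; returns (sequence, intron spans).

    Intron spans are 0-based half-open, relative to the genomic copy.
    """
    spliced = globulin_spliced_cds(group, copy_index)
    pieces: list[str] = []
    introns: list[tuple[int, int]] = []
    prev = 0
    offset = 0
    for codon_off, intron in zip(GLOBULIN_INTRON_CODON_OFFSETS, GLOBULIN_INTRONS):
        nt = codon_off * 3
        pieces.append(spliced[prev:nt])
        offset += nt - prev
        introns.append((offset, offset + len(intron)))
        pieces.append(intron)
        offset += len(intron)
        prev = nt
    pieces.append(spliced[prev:])
    return "".join(pieces), introns


# ---------------------------------------------------------------------------
# Alpha-amylase/trypsin inhibitors
# ---------------------------------------------------------------------------

AATI_FAMILIES = ("AATI-1", "AATI-2", "AATI-3", "AATI-unknown")

AATI_LEADER = "MASLKLVATLLVAAVLAGHHEAAMA"   # 25 aa; starts M A S
_AATI_MATURE_BASE = _random_protein("AATI/mature", 180)
_AATI_MATURE_LEN = {"AATI-1": 134, "AATI-2": 144, "AATI-3": 118, "AATI-unknown": 154}


def aati_protein(family: str) -> str:
    if family not in AATI_FAMILIES:
        raise ValueError(f"unknown AATI family {family!r}")
    mature = _diverge(_AATI_MATURE_BASE[:_AATI_MATURE_LEN[family]],
                      f"{family}/mature", 0.30, "AVTSGNDEFYHRKIW", protect="C")
    return AATI_LEADER + mature


def aati_cds(family: str, copy_index: int | None = None) -> str:
    return reverse_translate(aati_protein(family), copy_index,
                             AATI_START_CODONS) + STOP_CODON


# ---------------------------------------------------------------------------
# Non-gene elements: avenin gene fragment and avenin promoter
# ---------------------------------------------------------------------------

FRAGMENT_LEN_NT = 180


def fragment_cds(copy_index: int) -> str:
    """A truncated avenin-B 5' gene fragment (no complete ORF)."""
    # copy indices offset so fragment swaps never collide with real B copies
    return avenin_cds("avenin-B", copy_index=10 + copy_index)[:FRAGMENT_LEN_NT]


def _make_promoter(length: int = 400) -> str:
    rng = np.random.RandomState(zlib.crc32(b"avenin/promoter") % (2**31))
    seq = "".join("ACGT"[rng.randint(4)] for _ in range(length))
    while "ATG" in seq:          # keep the element ORF-free
        seq = seq.replace("ATG", "ACG")
    return seq


PROMOTER_SEQ = _make_promoter()

# ---------------------------------------------------------------------------
# Exemplars (classification references; synthetic stand-ins)
# ---------------------------------------------------------------------------

ALL_FAMILIES = AVENIN_FAMILIES + GLOBULIN_GROUPS + AATI_FAMILIES


def exemplar_sequences() -> list[tuple[str, str]]:
    """(family, nucleotide sequence) pairs used as classification exemplars.

    Globulin exemplars are genomic (intron-bearing) because the pipeline's
    consensus sequences are genomic as well.
    """
    out: list[tuple[str, str]] = []
    for fam in AVENIN_FAMILIES:
        out.append((fam, avenin_cds(fam, copy_index=None)))
    for grp in GLOBULIN_GROUPS:
        out.append((grp, globulin_genomic_cds(grp, copy_index=None)[0]))
    for fam in AATI_FAMILIES:
        out.append((fam, aati_cds(fam, copy_index=None)))
    return out


# ---------------------------------------------------------------------------
# Construction-time sanity checks (cheap; run once at import)
# ---------------------------------------------------------------------------

def _self_check() -> None:
    if translate("".join(AVENIN_START_CODONS)) != AVENIN_SIGNAL[:6]:
        raise AssertionError("avenin start codons disagree with signal peptide")
    if translate("".join(GLOBULIN_START_CODONS)) != GLOBULIN_SIGNAL[:8]:
        raise AssertionError("globulin start codons disagree with signal peptide")
    if translate("".join(AATI_START_CODONS)) != AATI_LEADER[:3]:
        raise AssertionError("AATI start codons disagree with leader peptide")
    for fam in AVENIN_FAMILIES:
        cds = avenin_cds(fam)
        if not degenerate_match(AVENIN_PROBE_TAIL, cds[:len(AVENIN_PROBE_TAIL)]):
            raise AssertionError(f"{fam} CDS does not carry the avenin probe motif")
        prot, bounds = avenin_protein(fam)
        n_cys = prot.count("C")
        expected = 9 if fam == "avenin-A" else 8
        if n_cys != expected:
            raise AssertionError(f"{fam}: {n_cys} cysteines, expected {expected}")
        if bounds["signal_peptide"] != (0, 19):
            raise AssertionError("avenin signal peptide must span (0, 19)")
    # no cross-family epitope contamination
    motifs = (EPITOPE_AVE_1A, EPITOPE_AVE_1B_VARIANT, EPITOPE_AVE_1C_VARIANT,
              EPITOPE_AVE_2, EPITOPE_GAMMA9B, "PYPEQEQPF", "PYPEQEQPI")
    owners = {
        EPITOPE_AVE_1A: "avenin-C2", EPITOPE_AVE_1B_VARIANT: "avenin-C1",
        EPITOPE_AVE_1C_VARIANT: "avenin-B", EPITOPE_AVE_2: "avenin-A",
        EPITOPE_GAMMA9B: "avenin-C2",
    }
    proteins = {fam: avenin_protein(fam)[0] for fam in AVENIN_FAMILIES}
    for grp in GLOBULIN_GROUPS:
        proteins[grp] = globulin_protein(grp)
    for fam in AATI_FAMILIES:
        proteins[fam] = aati_protein(fam)
    for motif in motifs:
        for fam, prot in proteins.items():
            present = motif in prot
            allowed = owners.get(motif) == fam
            if present and not allowed:
                raise AssertionError(f"epitope {motif} leaked into {fam}")


_self_check()
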