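"""Oligo design QC: consensus building, nearest-neighbor Tm, rule checks,
in-silico PCR, and the core-gene alignment filter.

Assay oligos are checked against the design rules used for the cif
assays: primer length 18–22 nt, GC 40–60%, a 3′ GC clamp of 2, Tm 58–62 °C
with ≤ 2 °C difference between the pair, poly-X runs ≤ 3; probes 18–30 nt,
Tm 65–70 °C, GC 30–80%, poly-X ≤ 5; amplicons 70–150 bp.

Melting temperatures use the SantaLucia unified nearest-neighbor
parameters with Tm = ΔH / (ΔS + R·ln(C_T/4)), an entropy salt correction,
and the von Ahsen monovalent-equivalent conversion for divalent cations
(Na_eq = monovalent + 120·sqrt(divalent − dNTP), all in mM).  The
nearest-neighbor evaluation is delegated to Biopython's
``MeltingTemp.Tm_NN``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

_DNA_UNAMBIGUOUS = set("ACGT")
_IUPAC = set("ACGTRYSWKMBDHVN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OligoSet:
    """One assay's primers and (optionally) hydrolysis probe, 5′→3′."""

    name: str
    forward: str
    reverse: str
    probe: Optional[str] = None
    declared_amplicon_bp: Optional[int] = None

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse), ("probe", self.probe)):
            if seq is None:
                continue
            if not seq:
                raise ValueError(f"{label} sequence must be non-empty")
            bad = set(seq.upper()) - _IUPAC
            if bad:
                raise ValueError(f"{label} contains non-IUPAC characters: {sorted(bad)}")


@dataclass(frozen=True)
class OligoConstraints:
    """Design-rule thresholds the oligos are audited against."""

    primer_len: Tuple[int, int] = (18, 22)
    amplicon_len: Tuple[int, int] = (70, 150)
    primer_gc: Tuple[float, float] = (40.0, 60.0)
    gc_clamp: int = 2
    primer_tm: Tuple[float, float] = (58.0, 62.0)
    max_tm_diff: float = 2.0
    primer_max_polyx: int = 3
    probe_len: Tuple[int, int] = (18, 30)
    probe_tm: Tuple[float, float] = (65.0, 70.0)
    probe_gc: Tuple[float, float] = (30.0, 80.0)
    probe_max_polyx: int = 5

    def __post_init__(self) -> None:
        for name in ("primer_len", "amplicon_len", "primer_gc", "primer_tm", "probe_len", "probe_tm", "probe_gc"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} interval must be non-degenerate")


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for Tm evaluation.

    Defaults follow the design-time convention: 50 mM monovalent salt,
    3 mM divalent, 0.8 mM dNTP, with oligo concentration 50 nM for
    primers (the Primer3-style annealing-oligo default) and 250 nM for
    probes (the concentration probes are actually run at).
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 3.0
    dntp_mM: float = 0.8
    primer_conc_nM: float = 50.0
    probe_conc_nM: float = 250.0

    def __post_init__(self) -> None:
        for name in ("monovalent_mM", "divalent_mM", "dntp_mM", "primer_conc_nM", "probe_conc_nM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def monovalent_equivalent_mM(self) -> float:
        """von Ahsen conversion: Na_eq = Na + 120·sqrt(max(Mg − dNTP, 0))."""
        return self.monovalent_mM + 120.0 * math.sqrt(max(self.divalent_mM - self.dntp_mM, 0.0))


#: bundled oligo sets for the cifA, cifB, and β-spectrin ddPCR assays
ASSAY_OLIGOS: Dict[str, OligoSet] = {
    "cifA": OligoSet(
        name="cifA",
        forward="GGTCCTTGGAATAATTTGCGG",
        reverse="TCAAACTCAGACTGTGGGC",
        probe="TTGCCACTTGATGGTTCTGGTGA",
        declared_amplicon_bp=83,
    ),
    "cifB": OligoSet(
        name="cifB",
        forward="GCAAGGTACTAGAGCACAGG",
        reverse="CACGAGCGTTGTTTCTACG",
        probe="AGGTGGTACTTCTACAGCACAAGG",
        declared_amplicon_bp=122,
    ),
    "beta_spec": OligoSet(
        name="beta_spec",
        forward="ATGACGACGGACATTTCGATTG",
        reverse="AACAGTCGGGAACTGGAGTTG",
        probe="GGTCCTGGCAACGAGTACATCGAT",
        declared_amplicon_bp=107,
    ),
}


def load_synthetic_reference_template() -> str:
    """Bundled synthetic β-spectrin template for in-silico PCR checks.

    A constructed (synthetic) stand-in for the real mRNA sequence: the
    bundled β-spectrin primers and probe are embedded at the declared
    spacing so the assay's 107 bp product is recoverable.
    """
    text = (
        resources.files("ddpcrkit.data")
        .joinpath("synthetic_beta_spec_template.fasta")
        .read_text()
    )
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


# ---------------------------------------------------------------------------
# consensus and alignment filtering
# ---------------------------------------------------------------------------

def consensus_with_n(alignment: Sequence[str]) -> str:
    """Consensus of an alignment with variable sites masked as ``N``.

    Per column: gap-majority columns are dropped; otherwise minority gaps
    are ignored, a single shared residue is emitted as-is, and two or
    more distinct residues become ``N``.
    """
    seqs = [s.upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least two aligned sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    out = []
    for col in zip(*seqs):
        gaps = sum(c in "-." for c in col)
        if gaps > len(col) / 2:
            continue
        residues = {c for c in col if c not in "-."}
        if not residues:
            continue
        out.append(residues.pop() if len(residues) == 1 else "N")
    return "".join(out)


def filter_alignment_genes(
    gene_alignments: Mapping[str, Sequence[str]]
) -> Tuple[List[str], Dict[str, str]]:
    """Frameshift/pseudogene filter for per-gene codon alignments.

    A gene is retained iff every gap run in every sequence has a length
    divisible by three (no frameshift) AND at most one sample contains
    any gap.  Returns the retained gene names and per-gene drop reasons.
    """
    retained: List[str] = []
    reasons: Dict[str, str] = {}
    for gene, seqs in gene_alignments.items():
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene!r}: ragged alignment")
        frameshift = False
        gapped_samples = 0
        for s in seqs:
            runs = [len(m.group(0)) for m in re.finditer(r"-+", s)]
            if runs:
                gapped_samples += 1
            if any(r % 3 != 0 for r in runs):
                frameshift = True
        if frameshift:
            reasons[gene] = "gap run length not a multiple of three"
        elif gapped_samples > 1:
            reasons[gene] = f"gaps in {gapped_samples} samples (max 1 allowed)"
        else:
            retained.append(gene)
    return retained, reasons


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------

def melting_temperature(
    seq: str,
    conditions: ThermoConditions = ThermoConditions(),
    oligo_conc_nM: Optional[float] = None,
) -> float:
    """Nearest-neighbor Tm (°C) of a primer/probe against its complement.

    SantaLucia unified ΔH/ΔS parameters with initiation terms; total
    strand concentration C_T enters as R·ln(C_T/4) (oligo in slight
    excess over template); the entropy-based salt correction uses the
    monovalent-equivalent concentration from
    :attr:`ThermoConditions.monovalent_equivalent_mM`.
    """
    s = seq.upper().strip()
    if len(s) < 8:
        raise ValueError("sequence must be at least 8 nt for a meaningful NN Tm")
    if set(s) - _DNA_UNAMBIGUOUS:
        raise ValueError("ambiguous or non-ACGT bases: Tm not evaluable")
    c_t = conditions.primer_conc_nM if oligo_conc_nM is None else oligo_conc_nM
    if c_t <= 0:
        raise ValueError("oligo concentration must be positive")
    # dnac1 = dnac2 = C_T/2 makes Biopython's k equal C_T/4
    return float(
        MeltingTemp.Tm_NN(
            s,
            nn_table=MeltingTemp.DNA_NN3,
            Na=conditions.monovalent_equivalent_mM,
            Mg=0,
            dNTPs=0,
            saltcorr=5,
            dnac1=c_t / 2,
            dnac2=c_t / 2,
            selfcomp=False,
        )
    )


# ---------------------------------------------------------------------------
# rule QC
# ---------------------------------------------------------------------------

@dataclass
class RuleCheck:
    """One evaluated design rule; ``passed=None`` marks an unevaluable rule."""

    oligo: str
    rule: str
    measured: Optional[float]
    bound: str
    passed: Optional[bool]


def _max_polyx(seq: str) -> int:
    return max(len(m.group(0)) for m in re.finditer(r"(.)\1*", seq))


def _in_window(value: float, window: Tuple[float, float]) -> bool:
    return window[0] <= value <= window[1]


def oligo_qc(
    oligos: OligoSet,
    constraints: OligoConstraints = OligoConstraints(),
    conditions: ThermoConditions = ThermoConditions(),
    template: Optional[str] = None,
) -> List[RuleCheck]:
    """Audit an oligo set against the design rules.

    Returns one :class:`RuleCheck` per rule per oligo.  Verdicts are
    case-insensitive in the input sequences.  Tm rules on oligos with
    ambiguity codes are reported as not evaluable (``passed=None``).
    With a template, the amplicon-size rule is evaluated by exact-match
    in-silico PCR.
    """
    checks: List[RuleCheck] = []
    primer_tms: Dict[str, Optional[float]] = {}

    for role, seq in (("forward", oligos.forward), ("reverse", oligos.reverse)):
        s = seq.upper()
        name = f"{oligos.name}.{role}"
        checks.append(RuleCheck(name, "length", len(s), f"[{constraints.primer_len[0]}, {constraints.primer_len[1]}] nt", _in_window(len(s), constraints.primer_len)))
        gc = 100.0 * gc_fraction(s)
        checks.append(RuleCheck(name, "gc_percent", round(gc, 2), f"[{constraints.primer_gc[0]}, {constraints.primer_gc[1]}] %", _in_window(gc, constraints.primer_gc)))
        clamp = s[-constraints.gc_clamp:]
        checks.append(RuleCheck(name, "gc_clamp", float(sum(c in "GC" for c in clamp)), f"3' {constraints.gc_clamp} bases all G/C", all(c in "GC" for c in clamp)))
        run = _max_polyx(s)
        checks.append(RuleCheck(name, "max_polyx", run, f"<= {constraints.primer_max_polyx}", run <= constraints.primer_max_polyx))
        try:
            tm = melting_temperature(s, conditions, conditions.primer_conc_nM)
            primer_tms[role] = tm
            checks.append(RuleCheck(name, "tm", round(tm, 2), f"[{constraints.primer_tm[0]}, {constraints.primer_tm[1]}] C", _in_window(tm, constraints.primer_tm)))
        except ValueError:
            primer_tms[role] = None
            checks.append(RuleCheck(name, "tm", None, "not evaluable (ambiguous bases)", None))

    if primer_tms.get("forward") is not None and primer_tms.get("reverse") is not None:
        diff = abs(primer_tms["forward"] - primer_tms["reverse"])
        checks.append(RuleCheck(f"{oligos.name}.pair", "tm_difference", round(diff, 2), f"<= {constraints.max_tm_diff} C", diff <= constraints.max_tm_diff))
    else:
        checks.append(RuleCheck(f"{oligos.name}.pair", "tm_difference", None, "not evaluable", None))

    if oligos.probe is not None:
        s = oligos.probe.upper()
        name = f"{oligos.name}.probe"
        checks.append(RuleCheck(name, "length", len(s), f"[{constraints.probe_len[0]}, {constraints.probe_len[1]}] nt", _in_window(len(s), constraints.probe_len)))
        gc = 100.0 * gc_fraction(s)
        checks.append(RuleCheck(name, "gc_percent", round(gc, 2), f"[{constraints.probe_gc[0]}, {constraints.probe_gc[1]}] %", _in_window(gc, constraints.probe_gc)))
        run = _max_polyx(s)
        checks.append(RuleCheck(name, "max_polyx", run, f"<= {constraints.probe_max_polyx}", run <= constraints.probe_max_polyx))
        try:
            tm = melting_temperature(s, conditions, conditions.probe_conc_nM)
            checks.append(RuleCheck(name, "tm", round(tm, 2), f"[{constraints.probe_tm[0]}, {constraints.probe_tm[1]}] C", _in_window(tm, constraints.probe_tm)))
        except ValueError:
            checks.append(RuleCheck(name, "tm", None, "not evaluable (ambiguous bases)", None))

    if template is not None:
        products = insilico_pcr(template, oligos.forward, oligos.reverse)
        if products:
            length = products[0][2]
            checks.append(RuleCheck(f"{oligos.name}.amplicon", "amplicon_length", length, f"[{constraints.amplicon_len[0]}, {constraints.amplicon_len[1]}] bp", _in_window(length, constraints.amplicon_len)))
        else:
            checks.append(RuleCheck(f"{oligos.name}.amplicon", "amplicon_length", None, "no product on template", False))
    return checks


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def _find_sites(
    template: str, pattern: str, max_mismatches: int, three_prime_is_right: bool
) -> List[int]:
    """Start indices (0-based) of pattern matches on the plus strand.

    In mismatch-tolerant mode the 3′-terminal 3 bases must match exactly
    (the extension end; mismatches there abolish amplification).
    """
    m, n = len(pattern), len(template)
    sites = []
    for i in range(n - m + 1):
        window = template[i : i + m]
        if max_mismatches == 0:
            if window == pattern:
                sites.append(i)
            continue
        mism = sum(a != b for a, b in zip(window, pattern))
        if mism > max_mismatches:
            continue
        three_prime = (
            zip(window[-3:], pattern[-3:]) if three_prime_is_right else zip(window[:3], pattern[:3])
        )
        if all(a == b for a, b in three_prime):
            sites.append(i)
    return sites


def insilico_pcr(
    template: str,
    forward: str,
    reverse: str,
    *,
    max_mismatches: int = 0,
    size_range: Tuple[int, int] = (40, 3000),
) -> List[Tuple[int, int, int]]:
    """Predict PCR products of a primer pair on a template.

    Finds forward-primer matches on the plus strand and
    reverse-complemented reverse-primer matches downstream; the amplicon
    spans from the forward primer's 5′ end to the reverse primer's 5′ end
    (both primers included).  Products within ``size_range`` are returned
    as 1-based inclusive ``(start, end, length)`` tuples sorted by start.
    Exact matching by default; ``max_mismatches`` ≤ 2 with an exact
    3′-terminal 3 bases enables cross-strain screening.

    No product yields an empty list, not an exception.
    """
    t = template.upper().replace("\n", "").replace(" ", "")
    fwd = forward.upper()
    rev_rc = str(Seq(reverse.upper()).reverse_complement())
    if len(t) < len(fwd) + len(rev_rc):
        raise ValueError("template shorter than the combined primer length")
    if max_mismatches < 0 or max_mismatches > 2:
        raise ValueError("max_mismatches must be 0..2")

    fwd_sites = _find_sites(t, fwd, max_mismatches, three_prime_is_right=True)
    # reverse primer anneals to the plus strand as its reverse complement;
    # its own 3' end corresponds to the left edge of the match
    rev_sites = _find_sites(t, rev_rc, max_mismatches, three_prime_is_right=False)

    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_rc)  # exclusive; reverse primer 5' end on plus strand
            length = end - f
            if r >= f and size_range[0] <= length <= size_range[1]:
                products.append((f + 1, end, length))
    products.sort()
    return products
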