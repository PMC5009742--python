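"""Template construction, duplex thermodynamics and cross-reactivity accounting.

An EXPAR template is a single DNA strand carrying two copies of the trigger's
reverse complement (X'), one at each terminus, separated by the complement of
a nicking-endonuclease recognition site plus a 4-nt post-cut spacer.  Once the
annealed trigger is extended into a double strand, the nicking enzyme
(Nt.BstNBI, top-strand site GAGTC, cut 4 nt downstream) releases a fresh
trigger-length copy.  Three template variants are modelled:

- ``standard``: the bare two-copy template;
- ``biotin``: the same sequence with a biotin tag recorded near the 5'
  terminus (default second base), which lowers the melting temperature of the
  unproductive 5' duplex and biases annealing toward the productive 3' copy;
- ``toehold_biotin``: additionally a dumbbell hairpin at the 3' terminus whose
  invading strand is six bases longer than the incumbent, acting as a
  thermodynamic filter against near-matched interferents.

Cross-reactivity is quantified from observed POIs: an interferent's apparent
copy number on the target's calibration line, as a percentage of its input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as mt

from .errors import DomainError, IngestError
from .quant import CalibrationFit, invert_poi

__all__ = [
    "NEASE_SITE_TOP",
    "NEASE_CUT_OFFSET",
    "LET7_FAMILY",
    "Toehold",
    "TemplateDesign",
    "InterferenceResult",
    "reverse_complement",
    "build_template",
    "validate_nease_site",
    "nn_duplex_tm",
    "interference_percent",
    "cross_reactivity_report",
]

#: Nt.BstNBI top-strand recognition sequence and nick offset (nt 3' of the
#: site's last base), from the enzyme's standard specification.
NEASE_SITE_TOP = "GAGTC"
NEASE_CUT_OFFSET = 4

#: Mature let-7 family sequences (miRBase), 5'->3' RNA.  let-7a is the assay
#: target; the others are its single- to few-nucleotide-variant siblings.
LET7_FAMILY = {
    "let-7a": "UGAGGUAGUAGGUUGUAUAGUU",
    "let-7b": "UGAGGUAGUAGGUUGUGUGGUU",
    "let-7c": "UGAGGUAGUAGGUUGUAUGGUU",
    "let-7d": "AGAGGUAGUAGGUUGCAUAGUU",
    "let-7e": "UGAGGUAGGAGGUUGUAUAGUU",
    "let-7f": "UGAGGUAGUAGAUUGUAUAGUU",
    "let-7g": "UGAGGUAGUAGUUUGUACAGUU",
    "let-7i": "UGAGGUAGUAGUUUGUGCUGUU",
}

_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RNA_TO_DNA_COMP = {"A": "T", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class Toehold:
    """Dumbbell-hairpin arms at the template's 3' terminus.

    ``invading`` is the template region the (correct) trigger engages —
    the open toehold plus the stem — and ``incumbent`` is the fold-back arm
    it displaces; the invader is six bases longer.
    """

    invading: str
    incumbent: str
    loop: str


@dataclass(frozen=True)
class TemplateDesign:
    """An assembled amplification template, 5'->3'."""

    target: str
    kind: str
    x_prime: str
    nease_site_complement: str
    spacer: str
    biotin_position: int | None
    toehold: Toehold | None
    core_template: str
    full_template: str


@dataclass(frozen=True)
class InterferenceResult:
    species: str
    poi: float
    apparent_copies: float
    interference_pct: float
    note: str = ""


def reverse_complement(seq: str, alphabet: str | None = None) -> str:
    """Watson-Crick reverse complement into DNA template space.

    DNA input gives the ordinary DNA reverse complement.  RNA input (U
    instead of T) is complemented into DNA (U pairs A, A pairs T), which is
    the strand a DNA template presents to an RNA trigger.  ``alphabet`` may
    be "DNA", "RNA", or None to infer from the presence of U/T.
    """
    up = seq.upper()
    if alphabet is None:
        alphabet = "RNA" if "U" in up else "DNA"
    if alphabet not in ("DNA", "RNA"):
        raise DomainError(f"unknown alphabet '{alphabet}'")
    table = _DNA_COMP if alphabet == "DNA" else _RNA_TO_DNA_COMP
    out = []
    for i, ch in enumerate(up):
        if ch not in table:
            raise DomainError(f"invalid {alphabet} character '{seq[i]}' at position {i + 1}")
        out.append(table[ch])
    return "".join(reversed(out))


def build_template(
    target: str,
    kind: str = "standard",
    spacer: str = "TCCA",
    biotin_position: int = 2,
    incumbent_length: int = 10,
    toehold_overhang: int = 6,
    loop: str = "TTTT",
    strict_length: bool = False,
) -> TemplateDesign:
    """Assemble an amplification template for a short oligonucleotide target.

    The core template is 5'-[X']-[rc(spacer)]-[rc(site)]-[X']-3', so the
    extended top strand reads 5'-[X]-[site]-[spacer]-[X]-3' and the nick
    falls exactly at the junction before the terminal trigger copy.  The
    spacer must be as long as the enzyme's cut offset (4 nt) for the
    released product to be trigger-length.

    ``kind`` selects the variant: ``biotin`` records a biotin at
    ``biotin_position`` (1-based from the 5' terminus); ``toehold_biotin``
    additionally appends a fold-back hairpin arm at the 3' terminus whose
    invader exceeds the incumbent by ``toehold_overhang`` bases.

    Targets outside the typical 18-25 nt short-oligonucleotide range draw a
    warning (or an error with ``strict_length``).
    """
    if kind not in ("standard", "biotin", "toehold_biotin"):
        raise DomainError(f"unknown template kind '{kind}'")
    n = len(target)
    if not 18 <= n <= 25:
        msg = f"target length {n} nt outside the typical 18-25 nt range"
        if strict_length:
            raise DomainError(msg)
        warnings.warn(msg, stacklevel=2)
    if len(spacer) != NEASE_CUT_OFFSET:
        warnings.warn(
            f"spacer length {len(spacer)} != cut offset {NEASE_CUT_OFFSET}; "
            "released product will not be trigger-length",
            stacklevel=2,
        )

    x_prime = reverse_complement(target)
    site_complement = reverse_complement(NEASE_SITE_TOP, "DNA")  # GACTC
    spacer = spacer.upper()
    core = x_prime + reverse_complement(spacer, "DNA") + site_complement + x_prime

    biotin_pos: int | None = None
    if kind in ("biotin", "toehold_biotin"):
        if not 1 <= biotin_position <= len(core):
            raise DomainError("biotin_position must fall inside the template")
        biotin_pos = biotin_position

    toehold: Toehold | None = None
    full = core
    if kind == "toehold_biotin":
        if incumbent_length < 1 or incumbent_length + toehold_overhang > len(x_prime):
            raise DomainError("incumbent/toehold lengths incompatible with target length")
        stem = core[-incumbent_length:]
        incumbent = reverse_complement(stem, "DNA")
        invading = core[-(incumbent_length + toehold_overhang):]
        toehold = Toehold(invading=invading, incumbent=incumbent, loop=loop.upper())
        full = core + toehold.loop + incumbent

    return TemplateDesign(
        target=target.upper(),
        kind=kind,
        x_prime=x_prime,
        nease_site_complement=site_complement,
        spacer=spacer,
        biotin_position=biotin_pos,
        toehold=toehold,
        core_template=core,
        full_template=full,
    )


def validate_nease_site(design: TemplateDesign) -> list[str]:
    """Check the nicking geometry of an assembled template.

    Scans the fully extended top strand (reverse complement of the core
    template) for the enzyme's recognition site and verifies that exactly
    one site exists, positioned so the nick releases a trigger-length
    product.  Returns a list of findings; an empty list means the design
    validates.
    """
    findings: list[str] = []
    top = reverse_complement(design.core_template, "DNA")
    positions = [i for i in range(len(top)) if top.startswith(NEASE_SITE_TOP, i)]
    if len(positions) == 0:
        findings.append("no top-strand recognition site found")
    elif len(positions) > 1:
        findings.append(f"{len(positions)} top-strand recognition sites found; expected exactly 1")
    else:
        cut = positions[0] + len(NEASE_SITE_TOP) + NEASE_CUT_OFFSET
        released = len(top) - cut
        if released != len(design.target):
            findings.append(
                f"nick releases {released} nt product; expected trigger length {len(design.target)}"
            )
    if NEASE_SITE_TOP in design.core_template:
        findings.append("template strand itself contains the recognition site (would be nicked)")
    return findings


def _aligned_complement_fraction(a: str, b_rev: str) -> float:
    pairs = sum(1 for x, y in zip(a, b_rev) if _DNA_COMP.get(x) == y)
    return pairs / max(len(a), 1)


def nn_duplex_tm(
    strand_a: str,
    strand_b: str,
    strand_conc: float = 2.5e-7,
    monovalent_salt: float = 0.05,
) -> float:
    """Nearest-neighbor duplex melting temperature (deg C).

    Both strands are given 5'->3'.  Thermodynamics are accumulated over
    nearest-neighbor stacks with initiation terms and monovalent-salt
    correction (unified DNA/DNA parameter set); internal and terminal
    mismatches are handled by the corresponding mismatch tables.  Intended
    for *ranking* designs — target/template hybrids are RNA/DNA in reality,
    so absolute values are approximate.

    ``strand_conc`` is the total strand concentration in molar;
    ``monovalent_salt`` in molar.
    """
    a, b = strand_a.upper(), strand_b.upper()
    if len(a) != len(b):
        raise DomainError("strands must be the same length for duplex Tm")
    if len(a) > 60:
        raise DomainError("nearest-neighbor model limited to <= 60 nt")
    b_aligned = b[::-1]  # 3'->5', aligned base-by-base with strand_a
    if _aligned_complement_fraction(a, b_aligned) < 0.5:
        raise DomainError("no complementary core between the strands")
    try:
        tm = mt.Tm_NN(
            a,
            c_seq=b_aligned,
            nn_table=mt.DNA_NN4,
            dnac1=strand_conc * 1e9 / 2.0,  # nM
            dnac2=strand_conc * 1e9 / 2.0,
            Na=monovalent_salt * 1e3,  # mM
            saltcorr=5,
        )
    except (KeyError, ValueError) as exc:
        raise DomainError(f"nearest-neighbor tables cannot score this duplex: {exc}") from exc
    return float(tm)


def interference_percent(
    poi_interferent: float,
    fit: CalibrationFit,
    input_copies: float,
    amplified: bool = True,
) -> float:
    """Cross-reaction of an interferent as % of its input copy number.

    The interferent's observed POI is converted to apparent copies on the
    target's calibration line; interference = apparent/input * 100.  A
    non-amplifying well contributes 0% (below the assay floor).
    """
    if input_copies <= 0:
        raise DomainError("input_copies must be positive")
    if not amplified:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # interferents sit far below range by design
        apparent = invert_poi(fit, poi_interferent)
    return apparent / input_copies * 100.0


def cross_reactivity_report(
    plate_results: pd.DataFrame,
    fit: CalibrationFit,
    input_copies: float,
    target_species: str = "let-7a",
) -> pd.DataFrame:
    """Per-species interference table from a specificity plate.

    ``plate_results`` needs columns ``species``, ``poi`` and ``amplified``
    (one row per well; replicate wells are averaged on POI).  Rows are
    sorted by interference, target first by construction (~100%).
    """
    required = {"species", "poi", "amplified"}
    if not required.issubset(plate_results.columns):
        raise IngestError(f"plate results must have columns {sorted(required)}")
    if target_species not in set(plate_results["species"]):
        raise IngestError(f"no target reference well for '{target_species}' on the plate")

    rows = []
    for species, grp in plate_results.groupby("species", sort=False):
        amped = grp[grp["amplified"].astype(bool)]
        if len(amped) == 0:
            rows.append(InterferenceResult(species, float("nan"), 0.0, 0.0,
                                           "non-amplifying (below floor)"))
            continue
        poi = float(amped["poi"].mean())
        pct = interference_percent(poi, fit, input_copies, amplified=True)
        apparent = pct / 100.0 * input_copies
        rows.append(InterferenceResult(species, poi, apparent, pct))
    table = pd.DataFrame([r.__dict__ for r in rows])
    return table.sort_values("interference_pct", ascending=False, ignore_index=True)
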