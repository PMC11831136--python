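"""Protocol-planning helpers: section counts and iRT peptide m/z values."""

from __future__ import annotations

import math

from pyteomics import mass as _mass
from pyteomics.auxiliary import PyteomicsError

from .errors import ValidationError

#: the spiked retention-time standard peptides monitored during LC-MS QC
IRT_PEPTIDES = (
    "LGGNEQVTR",
    "GAGSSEPVTGLDAK",
    "VEATFGVDESNAK",
    "YILAGVENSK",
    "TPVISGGPYEYR",
    "TPVITGAPYEYR",
    "DGLDAASYYAPVR",
    "ADVTPADFSEWSK",
    "GTFIIDPGGVIR",
    "GTFIIDPAAVIR",
    "LFLQFGAQGSPFLK",
)

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def section_count(tissue_length_mm: float, thickness_um: float) -> int:
    """Number of consecutive sections a tissue yields.

    floor(1000 * length_mm / thickness_um); e.g. a 3.5 mm muscle cut at
    20 um gives 175 sections.
    """
    if tissue_length_mm <= 0 or thickness_um <= 0:
        raise ValidationError("tissue length and thickness must be positive")
    return math.floor(1000.0 * tissue_length_mm / thickness_um)


def irt_mz(sequence: str, charge: int = 2) -> float:
    """Theoretical monoisotopic m/z of a tryptic peptide.

    (sum of monoisotopic residue masses + water + charge * proton) / charge,
    reported to 4 decimals — the convention of the retention-time standard
    tables used for LC performance monitoring.
    """
    if charge < 1:
        raise ValidationError("charge must be a positive integer")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in _STANDARD_RESIDUES:
            raise ValidationError(
                f"unknown residue {aa!r} at position {pos} of {sequence!r}"
            )
    try:
        mz = _mass.calculate_mass(sequence=sequence, charge=charge)
    except PyteomicsError as exc:  # defensive: residues validated above
        raise ValidationError(str(exc)) from exc
    return round(mz, 4)
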