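"""ICD-O-3 topography partition by endoscopic reach.

Flexible sigmoidoscopy examines the rectum, sigmoid and descending colon.
Tumors in those subsites can be seen on sigmoidoscopy; more proximal
subsites (cecum through splenic flexure) require a full colonoscopy.
Topography codes are normalized to dotless uppercase form ("C18.7" and
"c187" both mean sigmoid colon, code ``C187``).

Nine colorectal subsites are analyzed.  Codes outside them — including
non-specific sites such as C188 (overlapping lesion), C189 (colon NOS) and
C260 (intestinal tract NOS), and sites not screened per-segment such as
C181 (appendix) — are classified ``EXCLUDED``.  The splenic flexure (C185)
is classified as requiring colonoscopy even though some clinical series
treat it as borderline-reachable; per-segment reach variability is out of
scope here.
"""

from __future__ import annotations

import enum
import re
from pathlib import Path

__all__ = [
    "ReachCategory",
    "VISUALIZABLE_CODES",
    "COLONOSCOPY_CODES",
    "ANALYZED_CODES",
    "SUBSITE_LABELS",
    "normalize_topography",
    "classify_subsite",
    "subsite_label",
    "export_reach_map",
]

_TOPOGRAPHY_RE = re.compile(r"^C\d{2}\d?$")


class ReachCategory(str, enum.Enum):
    """Endoscopic-reach category of a colorectal subsite."""

    VISUALIZABLE = "VISUALIZABLE"
    REQUIRES_COLONOSCOPY = "REQUIRES_COLONOSCOPY"
    EXCLUDED = "EXCLUDED"


#: Subsites visible on flexible sigmoidoscopy (distal colorectum).
VISUALIZABLE_CODES = frozenset({"C186", "C187", "C199", "C209"})

#: Subsites requiring full colonoscopy (proximal to the descending colon).
COLONOSCOPY_CODES = frozenset({"C180", "C182", "C183", "C184", "C185"})

#: The nine analyzed colorectal subsites.
ANALYZED_CODES = VISUALIZABLE_CODES | COLONOSCOPY_CODES

#: Human-readable site names used in report tables.
SUBSITE_LABELS = {
    "C180": "Cecum",
    "C182": "Ascending Colon",
    "C183": "Hepatic Flexure",
    "C184": "Transverse Colon",
    "C185": "Splenic Flexure",
    "C186": "Descending Colon",
    "C187": "Sigmoid",
    "C199": "Rectosigmoid Junction",
    "C209": "Rectum",
}


def normalize_topography(code: str) -> str:
    """Normalize an ICD-O-3 topography string to dotless uppercase.

    Raises
    ------
    ValueError
        If the normalized string does not match ``C`` + 2-3 digits.
    """
    norm = str(code).strip().upper().replace(".", "")
    if not _TOPOGRAPHY_RE.match(norm):
        raise ValueError(f"invalid ICD-O-3 topography code: {code!r}")
    return norm


def classify_subsite(topography_code: str) -> ReachCategory:
    """Map a topography code to its endoscopic-reach category.

    Total and deterministic on syntactically valid codes: the four distal
    subsites are ``VISUALIZABLE``, the five proximal ones
    ``REQUIRES_COLONOSCOPY``, anything else ``EXCLUDED``.
    """
    norm = normalize_topography(topography_code)
    if norm in VISUALIZABLE_CODES:
        return ReachCategory.VISUALIZABLE
    if norm in COLONOSCOPY_CODES:
        return ReachCategory.REQUIRES_COLONOSCOPY
    return ReachCategory.EXCLUDED


def subsite_label(topography_code: str) -> str:
    """Human-readable name of one of the nine analyzed subsites."""
    norm = normalize_topography(topography_code)
    try:
        return SUBSITE_LABELS[norm]
    except KeyError:
        raise KeyError(
            f"{norm} is not among the nine analyzed colorectal subsites"
        ) from None


def export_reach_map(path: str | Path) -> None:
    """Write the code -> category -> label map as an auditable TSV."""
    lines = ["topography_code\treach_category\tlabel"]
    for code in sorted(ANALYZED_CODES):
        lines.append(f"{code}\t{classify_subsite(code).value}\t{SUBSITE_LABELS[code]}")
    Path(path).write_text("\n".join(lines) + "\n")
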