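"""ICD-10 chapter grouping for primary causes of death.

Codes are assigned to the chapter ranges used in cause-of-death
mortality tables (A00-B99 ... V01-Y98), with ischemic heart disease
(I20-I25) and heart failure (I50) additionally flagged as sub-ranges of
the circulatory chapter.  Unparseable codes map to ``unclassified``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

logger = logging.getLogger(__name__)

CHAPTERS = (
    ("A00-B99", ("A", 0), ("B", 99)),
    ("C00-D89", ("C", 0), ("D", 89)),
    ("E00-E90", ("E", 0), ("E", 90)),
    ("F00-F99", ("F", 0), ("F", 99)),
    ("G00-G99", ("G", 0), ("G", 99)),
    ("I00-I99", ("I", 0), ("I", 99)),
    ("J00-J99", ("J", 0), ("J", 99)),
    ("K00-K93", ("K", 0), ("K", 93)),
    ("L00-L99", ("L", 0), ("L", 99)),
    ("M00-M99", ("M", 0), ("M", 99)),
    ("N00-N99", ("N", 0), ("N", 99)),
    ("V01-Y98", ("V", 1), ("Y", 98)),
)

CHAPTER_NAMES = {
    "A00-B99": "Certain infectious and parasitic diseases",
    "C00-D89": "Neoplasms/Diseases of the blood and blood forming organs",
    "E00-E90": "Endocrine, nutritional and metabolic disorders",
    "F00-F99": "Mental and behavioural disorders",
    "G00-G99": "Diseases of the nervous system",
    "I00-I99": "Diseases of the circulatory system",
    "J00-J99": "Diseases of the respiratory system",
    "K00-K93": "Diseases of the digestive system",
    "L00-L99": "Diseases of the skin and subcutaneous tissue",
    "M00-M99": "Diseases of the musculoskeletal system and connective tissue",
    "N00-N99": "Diseases of the genitourinary system",
    "V01-Y98": "External causes of morbidity and mortality",
}

_CODE_RE = re.compile(r"^([A-Z])(\d{1,2})")


@dataclass(frozen=True)
class ChapterAssignment:
    chapter: str
    ischemic: bool = False   # I20-I25 sub-range
    heart_failure: bool = False  # I50


def map_icd10_chapter(code: str) -> ChapterAssignment:
    """Assign an ICD-10 code to its mortality-table chapter.

    Sub-range flags mark ischemic heart disease (I20-I25) and heart
    failure (I50).  Codes that do not parse, or fall outside every
    tabulated range, return ``unclassified``.
    """
    text = str(code).strip().upper() if code is not None else ""
    m = _CODE_RE.match(text)
    if not m:
        if text:  # an empty code is just a missing cause
            logger.warning("unparseable ICD-10 code %r", code)
        return ChapterAssignment("unclassified")
    letter, num = m.group(1), int(m.group(2))
    key = (letter, num)
    for label, lo, hi in CHAPTERS:
        if lo <= key <= hi:
            return ChapterAssignment(
                chapter=label,
                ischemic=(letter == "I" and 20 <= num <= 25),
                heart_failure=(letter == "I" and num == 50),
            )
    return ChapterAssignment("unclassified")
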