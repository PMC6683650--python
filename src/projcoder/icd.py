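"""ICD-10-CM three-character categories, chapter ranges, and the label
hierarchy used by the coder's max-pooling stages.

Three-character category codes (e.g. ``C17``) group into two-character
prefixes (``C1``) and into the 21 chapter ranges (``C00-D49``).  The
external-causes chapter ``V00-Y99`` is flagged as excluded: its codes are
parsed but marked so callers can drop them rather than silently lose them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "ICDCode",
    "ICDHierarchy",
    "DischargeNote",
    "parse_icd",
    "load_chapter_table",
    "build_hierarchy",
    "EXCLUDED_CHAPTER",
]

EXCLUDED_CHAPTER = "V00-Y99"

_CODE_RE = re.compile(r"^[A-Z][0-9A-Z]{2}$")


def _char_key(ch: str) -> int:
    # ICD ordering: digits 0-9 sort before letters A-Z (O99 < O9A)
    return int(ch) if ch.isdigit() else 10 + ord(ch) - ord("A")


def _code_key(code: str) -> tuple[int, ...]:
    return tuple(_char_key(c) for c in code)


def load_chapter_table(path: str | Path | None = None) -> list[tuple[str, str, str]]:
    """Load the (chapter label, range start, range end) table.

    Defaults to the bundled 21-chapter ICD-10-CM table.
    """
    if path is None:
        text = resources.files("projcoder.data").joinpath("icd_chapters.tsv").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = []
    for line in text.splitlines():
        if not line.strip():
            continue
        label, start, end = line.split("\t")
        rows.append((label, start, end))
    return rows


_CHAPTERS = load_chapter_table()


@dataclass(frozen=True)
class ICDCode:
    """A three-character ICD-10-CM category with its hierarchy coordinates."""

    code: str
    two_char: str
    chapter: str
    excluded: bool = False

    def __str__(self) -> str:
        return self.code

    def __eq__(self, other) -> bool:
        if isinstance(other, ICDCode):
            return self.code == other.code
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.code)

    def __lt__(self, other: "ICDCode") -> bool:
        return self.code < other.code


def parse_icd(raw: str) -> ICDCode:
    """Normalize a raw code string to its three-character category.

    Strips any dot-suffix, uppercases, truncates to three characters and
    resolves the chapter.  Codes in the excluded external-causes chapter are
    returned flagged rather than dropped.  An unresolvable code raises
    ``ValueError``.
    """
    if not raw or not raw.strip():
        raise ValueError("empty ICD code")
    code = raw.strip().upper().split(".")[0][:3]
    if not _CODE_RE.match(code):
        raise ValueError(f"not a three-character ICD-10-CM category: {raw!r}")
    key = _code_key(code)
    for label, start, end in _CHAPTERS:
        if _code_key(start) <= key <= _code_key(end):
            return ICDCode(code, code[:2], label, excluded=(label == EXCLUDED_CHAPTER))
    raise ValueError(f"code {code!r} falls in no ICD-10-CM chapter range")


@dataclass
class DischargeNote:
    """A tokenized discharge note carrying a set of three-character codes."""

    tokens: list[str]
    codes: set[ICDCode]


@dataclass
class ICDHierarchy:
    """Chapter and two-character groupings over a concrete code inventory.

    ``code_index`` gives each code's output position within its chapter
    classifier (codes sorted lexicographically within a chapter).
    """

    chapters: dict[str, list[ICDCode]]
    two_char_groups: dict[str, list[ICDCode]]
    code_index: dict[ICDCode, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.code_index:
            for codes in self.chapters.values():
                for i, c in enumerate(codes):
                    self.code_index[c] = i

    @property
    def codes(self) -> list[ICDCode]:
        return [c for codes in self.chapters.values() for c in codes]

    def chapter_of(self, code: ICDCode) -> str:
        return code.chapter


def build_hierarchy(codes) -> ICDHierarchy:
    """Build the two-level hierarchy over an iterable of ``ICDCode``.

    Each code belongs to exactly one two-character group and one chapter, so
    the two grouping levels each partition the code set.
    """
    uniq = sorted(set(codes))
    if not uniq:
        raise ValueError("no codes to build a hierarchy from")
    chapters: dict[str, list[ICDCode]] = {}
    groups: dict[str, list[ICDCode]] = {}
    for c in uniq:
        chapters.setdefault(c.chapter, []).append(c)
        groups.setdefault(c.two_char, []).append(c)
    return ICDHierarchy(chapters, groups)
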