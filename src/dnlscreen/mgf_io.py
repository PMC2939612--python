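"""Reading and writing Mascot Generic Format (MGF) peak lists.

MGF is the plain-text interchange format used by proteomics search
engines: each tandem mass spectrum is a ``BEGIN IONS`` .. ``END IONS``
block of ``KEY=value`` header lines followed by whitespace-separated
``m/z abundance`` peak lines.

The reader is deliberately tolerant of real-world files (unknown header
keys, extra peak-line columns, CR/LF endings, trailing blank lines) but
reports structural damage — an ``END IONS`` with no matching ``BEGIN``,
an unparseable peak line — as :class:`MGFParseError` carrying the
offending line number.  In ``errors="skip"`` mode a damaged block is
dropped with a warning and iteration continues at the next block, which
is what batch screening of large merged files needs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, NamedTuple, Optional, TextIO, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Spectrum",
    "LabelTable",
    "MGFParseError",
    "read_mgf",
    "write_mgf",
    "read_labels",
    "CATEGORIES",
    "CHARGE_CLASSES",
]

#: Search-outcome categories used by the evaluation module: true-positive
#: peptide match, decoy (false-positive) match, or no significant match.
CATEGORIES = ("TP", "FP", "unidentified")

#: Precursor-charge strata for evaluation: singly charged vs doubly/triply.
CHARGE_CLASSES = ("single", "multi")


class Peak(NamedTuple):
    """A single peak: m/z in Thomson, abundance in arbitrary intensity units."""

    mz: float
    abundance: float


@dataclass
class Spectrum:
    """One MS/MS scan as read from (or destined for) an MGF file.

    Parameters
    ----------
    identifier
        The MGF ``TITLE``; synthesized as ``"index=<source_index>"`` when
        the file has none, so spectra stay joinable to label tables.
    precursor_mz
        First number of the ``PEPMASS`` line (Th), if present.
    precursor_charge
        Signed charges from the ``CHARGE`` line (``2+ and 3+`` -> [2, 3]).
    peaks
        ``(m/z, abundance)`` pairs in file order; sorting is the scanning
        module's job, never the reader's.
    source_index
        Zero-based position of the block in its source file.
    params
        Unrecognized ``KEY=value`` header lines, preserved for round-trips.
    """

    identifier: str
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[list[int]] = None
    peaks: list[Peak] = field(default_factory=list)
    source_index: int = 0
    precursor_intensity: Optional[float] = None
    params: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("Spectrum identifier must be non-empty")
        for p in self.peaks:
            if p.mz <= 0:
                raise ValueError(f"non-positive m/z {p.mz!r} in {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        """Copy of this spectrum with a different peak list, metadata kept."""
        return replace(self, peaks=list(peaks))


class MGFParseError(ValueError):
    """Structural problem in an MGF file, tied to a 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


_CHARGE_TOKEN = re.compile(r"(\d+)\s*([+-]?)")


def _parse_charge(value: str) -> list[int]:
    charges = []
    for num, sign in _CHARGE_TOKEN.findall(value):
        charges.append(-int(num) if sign == "-" else int(num))
    return charges


def _parse_block(
    header: list[tuple[int, str]],
    peak_lines: list[tuple[int, str]],
    source_index: int,
) -> Spectrum:
    title: Optional[str] = None
    pepmass: Optional[float] = None
    pepmass_intensity: Optional[float] = None
    charge: Optional[list[int]] = None
    params: dict[str, str] = {}

    for lineno, line in header:
        key, _, value = line.partition("=")
        key = key.strip().upper()
        value = value.strip()
        if key == "TITLE":
            title = value
        elif key == "PEPMASS":
            fields = value.split()
            try:
                pepmass = float(fields[0])
            except (IndexError, ValueError):
                raise MGFParseError(f"unparseable PEPMASS {value!r}", lineno)
            if len(fields) > 1:
                try:
                    pepmass_intensity = float(fields[1])
                except ValueError:
                    pepmass_intensity = None
        elif key == "CHARGE":
            charge = _parse_charge(value) or None
        else:
            params[key] = value

    peaks: list[Peak] = []
    for lineno, line in peak_lines:
        fields = line.split()
        try:
            mz, abundance = float(fields[0]), float(fields[1])
        except (IndexError, ValueError):
            raise MGFParseError(f"unparseable peak line {line!r}", lineno)
        if mz <= 0:
            raise MGFParseError(f"non-positive m/z in peak line {line!r}", lineno)
        peaks.append(Peak(mz, abundance))

    return Spectrum(
        identifier=title if title else f"index={source_index}",
        precursor_mz=pepmass,
        precursor_charge=charge,
        peaks=peaks,
        source_index=source_index,
        precursor_intensity=pepmass_intensity,
        params=params,
    )


def read_mgf(
    source: Union[str, Path, TextIO],
    errors: str = "raise",
    on_skip: Optional[Callable[[MGFParseError], None]] = None,
) -> Iterator[Spectrum]:
    """Lazily yield one :class:`Spectrum` per ``BEGIN IONS`` block.

    Parameters
    ----------
    source
        Path to an MGF file, or an open text handle.
    errors
        ``"raise"`` (default) propagates :class:`MGFParseError`;
        ``"skip"`` logs a warning, calls *on_skip* if given, and resumes
        at the next block.
    """
    if errors not in ("raise", "skip"):
        raise ValueError(f"errors must be 'raise' or 'skip', got {errors!r}")

    if hasattr(source, "read"):
        yield from _read_handle(source, errors, on_skip)
    else:
        with open(source, "r", encoding="utf-8") as handle:
            yield from _read_handle(handle, errors, on_skip)


def _read_handle(handle, errors, on_skip) -> Iterator[Spectrum]:
    source_index = 0
    in_block = False
    begin_line = 0
    header: list[tuple[int, str]] = []
    peak_lines: list[tuple[int, str]] = []

    def fail(exc: MGFParseError) -> Iterator[Spectrum]:
        if errors == "raise":
            raise exc
        logger.warning("skipping malformed MGF block: %s", exc)
        if on_skip is not None:
            on_skip(exc)
        return iter(())

    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if in_block:
                yield from fail(
                    MGFParseError(
                        f"BEGIN IONS inside unterminated block from line {begin_line}",
                        lineno,
                    )
                )
            in_block, begin_line = True, lineno
            header, peak_lines = [], []
        elif line == "END IONS":
            if not in_block:
                yield from fail(MGFParseError("END IONS without BEGIN IONS", lineno))
                continue
            in_block = False
            try:
                yield _parse_block(header, peak_lines, source_index)
            except MGFParseError as exc:
                yield from fail(exc)
            source_index += 1
        elif in_block:
            if line[0].isdigit() or line[0] in "+-.":
                peak_lines.append((lineno, line))
            else:
                header.append((lineno, line))
        # lines outside any block (e.g. global MGF parameters) are ignored

    if in_block:
        yield from fail(
            MGFParseError("unterminated BEGIN IONS block", begin_line)
        )


def _format_charge(charges: list[int]) -> str:
    return " and ".join(f"{abs(c)}{'-' if c < 0 else '+'}" for c in charges)


def write_mgf(spectra: Iterable[Spectrum], sink: Union[str, Path, TextIO]) -> int:
    """Write spectra as MGF; returns the number written.

    Numbers are rendered with 10 significant digits so a
    ``read_mgf(write_mgf(...))`` round trip preserves peak values to well
    within 1e-6 relative.
    """
    if hasattr(sink, "write"):
        return _write_handle(spectra, sink)
    with open(sink, "w", encoding="utf-8", newline="\n") as handle:
        return _write_handle(spectra, handle)


def _write_handle(spectra: Iterable[Spectrum], handle: TextIO) -> int:
    count = 0
    for spectrum in spectra:
        handle.write("BEGIN IONS\n")
        handle.write(f"TITLE={spectrum.identifier}\n")
        if spectrum.precursor_mz is not None:
            pepmass = format(spectrum.precursor_mz, ".10g")
            if spectrum.precursor_intensity is not None:
                pepmass += f" {format(spectrum.precursor_intensity, '.10g')}"
            handle.write(f"PEPMASS={pepmass}\n")
        if spectrum.precursor_charge:
            handle.write(f"CHARGE={_format_charge(spectrum.precursor_charge)}\n")
        for key, value in spectrum.params.items():
            handle.write(f"{key}={value}\n")
        for peak in spectrum.peaks:
            handle.write(
                f"{format(peak.mz, '.10g')} {format(peak.abundance, '.10g')}\n"
            )
        handle.write("END IONS\n")
        count += 1
    return count


@dataclass
class LabelTable:
    """Search-outcome labels keyed by spectrum identifier.

    ``category`` maps identifier -> one of :data:`CATEGORIES`;
    ``charge_class`` (optionally) maps identifier -> one of
    :data:`CHARGE_CLASSES` for charge-stratified evaluation.
    """

    category: dict[str, str] = field(default_factory=dict)
    charge_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ident, cat in self.category.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for {ident!r}")
        for ident, cls in self.charge_class.items():
            if cls not in CHARGE_CLASSES:
                raise ValueError(f"unknown charge class {cls!r} for {ident!r}")

    def __len__(self) -> int:
        return len(self.category)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.category

    def subset(self, charge_class: str) -> "LabelTable":
        """Labels restricted to one charge class."""
        if charge_class not in CHARGE_CLASSES:
            raise ValueError(f"unknown charge class {charge_class!r}")
        keep = {i for i, c in self.charge_class.items() if c == charge_class}
        return LabelTable(
            category={i: c for i, c in self.category.items() if i in keep},
            charge_class={i: charge_class for i in keep},
        )


_CATEGORY_FOLD = {c.lower(): c for c in CATEGORIES}
_CLASS_FOLD = {c.lower(): c for c in CHARGE_CLASSES}


def read_labels(source: Union[str, Path, TextIO]) -> LabelTable:
    """Read a tab-separated label table: identifier, category[, charge_class].

    Category tokens are case-insensitive; lines starting with ``#`` and
    blank lines are skipped.  Unknown categories and duplicate
    identifiers are fatal, naming the offending line.
    """
    if hasattr(source, "read"):
        return _read_labels_handle(source)
    with open(source, "r", encoding="utf-8") as handle:
        return _read_labels_handle(handle)


def _read_labels_handle(handle: TextIO) -> LabelTable:
    category: dict[str, str] = {}
    charge_class: dict[str, str] = {}
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected at least 2 tab-separated fields")
        ident = fields[0].strip()
        cat_token = fields[1].strip().lower()
        if cat_token not in _CATEGORY_FOLD:
            raise ValueError(f"line {lineno}: unknown category {fields[1].strip()!r}")
        if ident in category:
            raise ValueError(f"line {lineno}: duplicate identifier {ident!r}")
        category[ident] = _CATEGORY_FOLD[cat_token]
        if len(fields) >= 3 and fields[2].strip():
            cls_token = fields[2].strip().lower()
            if cls_token not in _CLASS_FOLD:
                raise ValueError(
                    f"line {lineno}: unknown charge class {fields[2].strip()!r}"
                )
            charge_class[ident] = _CLASS_FOLD[cls_token]
    return LabelTable(category=category, charge_class=charge_class)


def write_labels(table: LabelTable, sink: Union[str, Path, TextIO]) -> int:
    """Write a label table as TSV; returns the number of rows."""
    if hasattr(sink, "write"):
        return _write_labels_handle(table, sink)
    with open(sink, "w", encoding="utf-8", newline="\n") as handle:
        return _write_labels_handle(table, handle)


def _write_labels_handle(table: LabelTable, handle: TextIO) -> int:
    count = 0
    for ident, cat in table.category.items():
        cls = table.charge_class.get(ident)
        handle.write(f"{ident}\t{cat}" + (f"\t{cls}" if cls else "") + "\n")
        count += 1
    return count
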