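"""Resonance library: per-CH-moiety chemical shifts and 13C/13C couplings.

Each record describes one *proton* resonance — a carbon with two
diastereotopic protons (e.g. glutamate C3) contributes two entries, C3a and
C3b, sharing the carbon shift and coupling constants.  The library drives
the search-window placement and the multiplet simulation; its values come
from public compilations (HMDB/BMRB) and are configuration data, not code.

File format (CSV, versioned header comment)::

    # hsqcmultiplet-library v1
    metabolite,moiety,delta_h,delta_c,couplings
    lactate,C2,4.10,69.3,C1:54.0;C3:37.0

``couplings`` is semicolon-separated ``partner:J[:lr]`` with J in Hz; the
optional ``lr`` marks a long-range coupling, excluded from multiplet
enumeration unless the analysis is configured to keep it.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from .config import logger

LIBRARY_FORMAT_VERSION = 1


class LibraryError(ValueError):
    """Malformed library file or violated library invariant."""


@dataclass(frozen=True)
class Coupling:
    partner: str
    j: float           # Hz
    one_bond: bool = True


@dataclass(frozen=True)
class ResonanceEntry:
    """One CH moiety: library shifts plus its 13C/13C coupling constants."""

    metabolite: str
    moiety: str
    delta_h_lib: float
    delta_c_lib: float
    couplings: Tuple[Coupling, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_h_lib <= 13.0:
            raise LibraryError(
                f"{self.metabolite}/{self.moiety}: 1H shift {self.delta_h_lib} "
                "outside [0, 13] ppm")
        if not 0.0 <= self.delta_c_lib <= 220.0:
            raise LibraryError(
                f"{self.metabolite}/{self.moiety}: 13C shift {self.delta_c_lib} "
                "outside [0, 220] ppm")
        for c in self.couplings:
            if c.j <= 0:
                raise LibraryError(
                    f"{self.metabolite}/{self.moiety}: non-positive coupling "
                    f"J({c.partner}) = {c.j} Hz")

    def one_bond_couplings(self) -> Tuple[Coupling, ...]:
        return tuple(c for c in self.couplings if c.one_bond)

    @property
    def key(self) -> Tuple[str, str]:
        return (self.metabolite, self.moiety)


class ResonanceLibrary:
    """Indexed collection of :class:`ResonanceEntry`."""

    def __init__(self, entries: List[ResonanceEntry]):
        self._by_key: Dict[Tuple[str, str], ResonanceEntry] = {}
        self._by_metabolite: Dict[str, List[ResonanceEntry]] = {}
        for e in entries:
            if e.key in self._by_key:
                raise LibraryError(f"duplicate entry {e.metabolite}/{e.moiety}")
            self._by_key[e.key] = e
            self._by_metabolite.setdefault(e.metabolite.lower(), []).append(e)
        for v in self._by_metabolite.values():
            v.sort(key=lambda e: e.moiety)

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(sorted(self._by_key.values(), key=lambda e: e.key))

    @property
    def metabolites(self) -> List[str]:
        return sorted(self._by_metabolite)

    def resonances_of(self, metabolite: str) -> List[ResonanceEntry]:
        """All CH entries of *metabolite*, ordered by moiety label."""
        name = metabolite.lower()
        if name not in self._by_metabolite:
            near = difflib.get_close_matches(name, self._by_metabolite, n=3)
            hint = f"; did you mean {', '.join(near)}?" if near else ""
            raise KeyError(f"unknown metabolite {metabolite!r}{hint}")
        return list(self._by_metabolite[name])


def _parse_couplings(text: str, where: str) -> Tuple[Coupling, ...]:
    couplings = []
    text = text.strip()
    if not text:
        return ()
    for token in text.split(";"):
        parts = token.strip().split(":")
        if len(parts) not in (2, 3):
            raise LibraryError(f"{where}: malformed coupling {token!r}")
        partner = parts[0].strip()
        try:
            j = float(parts[1])
        except ValueError:
            raise LibraryError(f"{where}: non-numeric J in {token!r}")
        one_bond = True
        if len(parts) == 3:
            if parts[2].strip() != "lr":
                raise LibraryError(f"{where}: unknown coupling flag {parts[2]!r}")
            one_bond = False
        couplings.append(Coupling(partner, j, one_bond))
    return tuple(couplings)


def load_library(path: Union[str, Path]) -> ResonanceLibrary:
    """Load and validate a CSV resonance library."""
    path = Path(path)
    entries: List[ResonanceEntry] = []
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.startswith("#") or "hsqcmultiplet-library" not in first:
            raise LibraryError(f"{path}: missing library version header")
        reader = csv.DictReader(fh)
        required = {"metabolite", "moiety", "delta_h", "delta_c", "couplings"}
        if reader.fieldnames is None:
            logger.warning("library file %s is empty", path)
            return ResonanceLibrary([])
        if not required.issubset(reader.fieldnames):
            raise LibraryError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=3):
            where = f"{path}:{lineno}"
            try:
                entry = ResonanceEntry(
                    metabolite=row["metabolite"].strip().lower(),
                    moiety=row["moiety"].strip(),
                    delta_h_lib=float(row["delta_h"]),
                    delta_c_lib=float(row["delta_c"]),
                    couplings=_parse_couplings(row["couplings"] or "", where),
                )
            except (TypeError, ValueError) as exc:
                if isinstance(exc, LibraryError):
                    raise
                raise LibraryError(f"{where}: malformed record ({exc})")
            entries.append(entry)
    if not entries:
        logger.warning("library file %s contains no entries", path)
    return ResonanceLibrary(entries)


def default_library_path() -> Path:
    return Path(str(resources.files("hsqcmultiplet").joinpath("data/default_library.csv")))


def default_library() -> ResonanceLibrary:
    """The shipped library for the four standard test metabolites."""
    return load_library(default_library_path())
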