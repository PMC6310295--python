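"""The 55-protein angiogenesis panel.

A :class:`ProteinPanel` is an ordered list of analytes spotted on the
membrane.  The bundled default reproduces the analyte list of the
commercial human angiogenesis antibody array (55 unique proteins, in
alphabetical order), with vendor synonyms and ASCII fallbacks for the
Greek-lettered names kept as aliases.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import SchemaError

__all__ = ["PanelEntry", "ProteinPanel", "load_panel", "default_panel"]


def _norm(name: str) -> str:
    """Whitespace-normalized form used for comparisons."""
    return " ".join(name.split())


@dataclass(frozen=True)
class PanelEntry:
    name: str
    aliases: tuple[str, ...]
    index: int


@dataclass(frozen=True)
class ProteinPanel:
    """Ordered, validated list of panel proteins."""

    entries: tuple[PanelEntry, ...]
    _by_name: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise SchemaError("panel has no entries")
        names = [_norm(e.name) for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate protein names in panel: {dupes}")
        indices = [e.index for e in self.entries]
        if len(set(indices)) != len(indices):
            raise SchemaError("duplicate protein indices in panel")
        lookup: dict[str, PanelEntry] = {}
        for e in self.entries:
            lookup[_norm(e.name)] = e
            for a in e.aliases:
                lookup.setdefault(_norm(a), e)
        object.__setattr__(self, "_by_name", lookup)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __contains__(self, name: str) -> bool:
        return _norm(name) in self._by_name

    def resolve(self, name: str) -> PanelEntry:
        """Look up an entry by canonical name or any alias."""
        try:
            return self._by_name[_norm(name)]
        except KeyError:
            raise KeyError(f"protein {name!r} not in panel") from None


def load_panel(path: str | Path) -> ProteinPanel:
    """Read a panel CSV (columns ``name, aliases, index``; aliases
    semicolon-separated) and validate uniqueness of names and indices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"name": str, "aliases": str, "index": "Int64"})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"panel file {path} is empty") from None
    missing = {"name", "aliases", "index"} - set(df.columns)
    if missing:
        raise SchemaError(f"panel file {path} lacks columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        if pd.isna(row.name) or not str(row.name).strip():
            raise SchemaError("panel row with empty protein name")
        aliases = ()
        if isinstance(row.aliases, str) and row.aliases.strip():
            aliases = tuple(a.strip() for a in row.aliases.split(";") if a.strip())
        if pd.isna(row.index):
            raise SchemaError(f"panel row {row.name!r} lacks an index")
        entries.append(PanelEntry(name=str(row.name).strip(), aliases=aliases, index=int(row.index)))
    return ProteinPanel(entries=tuple(entries))


def default_panel() -> ProteinPanel:
    """The bundled 55-protein angiogenesis panel."""
    with importlib.resources.as_file(
        importlib.resources.files("angioarray.data") / "panel.csv"
    ) as p:
        return load_panel(p)
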