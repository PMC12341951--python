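"""Membrane headgroup composition tables and deterministic lipid-count allocation.

Ships the two built-in phospholipid headgroup compositions used throughout:
a jojoba-like mixture (PC:PE:PI:PG = 45:38:10:7) and an *N. tabacum*-like
mixture (PC:PE:PA:PG:PI:PS = 60:59:37:26:15:3).  Ratio parts are normalized
to fractions, so the tables work identically whether read as counts or ratios.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import yaml

HEADGROUPS = ("PC", "PE", "PI", "PG", "PA", "PS")


@dataclass(frozen=True)
class CompositionTable:
    """Ordered (headgroup, ratio-part) entries; order is preserved as listed."""

    name: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for code, parts in self.entries:
            if code not in HEADGROUPS:
                raise ValueError(f"unknown headgroup code {code!r}")
            if parts < 0:
                raise ValueError(f"negative ratio part for {code}")
        if sum(p for _, p in self.entries) <= 0:
            raise ValueError("composition has no positive parts")

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(p for _, p in self.entries)
        return {code: p / total for code, p in self.entries}

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "CompositionTable":
        """Load from YAML (mapping or entry list) or CSV (`headgroup,parts`)."""
        path = Path(path)
        if path.suffix.lower() in {".yaml", ".yml"}:
            data = yaml.safe_load(path.read_text())
            if isinstance(data, dict):
                entries = tuple((str(k), float(v)) for k, v in data.items())
            else:
                entries = tuple((str(d["headgroup"]), float(d["parts"])) for d in data)
        else:
            with open(path) as fh:
                rows = list(csv.DictReader(fh))
            entries = tuple((r["headgroup"].strip(), float(r["parts"])) for r in rows)
        return cls(name or path.stem, entries)


JOJOBA = CompositionTable("jojoba", (("PC", 45), ("PE", 38), ("PI", 10), ("PG", 7)))
TABACUM = CompositionTable(
    "tabacum",
    (("PC", 60), ("PE", 59), ("PA", 37), ("PG", 26), ("PI", 15), ("PS", 3)),
)

BUILTIN_TABLES = {"jojoba": JOJOBA, "tabacum": TABACUM}


def get_table(table: "CompositionTable | str") -> CompositionTable:
    if isinstance(table, CompositionTable):
        return table
    try:
        return BUILTIN_TABLES[table]
    except KeyError:
        raise KeyError(
            f"unknown composition {table!r}; built-ins: {sorted(BUILTIN_TABLES)}"
        ) from None


def allocate_counts(table: CompositionTable | str, n_lipids: int) -> dict[str, int]:
    """Largest-remainder (Hare) allocation of ``n_lipids`` across headgroups.

    Each species gets floor(fraction * n); the shortfall is handed out one by
    one to the largest fractional remainders, ties broken by listed order.
    The returned counts sum to ``n_lipids`` exactly.
    """
    table = get_table(table)
    if n_lipids <= 0:
        raise ValueError("n_lipids must be positive")
    n_nonzero = sum(1 for _, p in table.entries if p > 0)
    if n_lipids < n_nonzero:
        raise ValueError(
            f"{n_lipids} lipids cannot host >= 1 of each of {n_nonzero} species"
        )
    fractions = table.fractions
    quotas = {code: fractions[code] * n_lipids for code, _ in table.entries}
    counts = {code: int(quotas[code]) for code, _ in table.entries}
    shortfall = n_lipids - sum(counts.values())
    order = sorted(
        range(len(table.entries)),
        key=lambda i: (-(quotas[table.entries[i][0]] - counts[table.entries[i][0]]), i),
    )
    for i in order[:shortfall]:
        counts[table.entries[i][0]] += 1
    return counts


def scenario_grid(
    proteins: list[str],
    tables: list[CompositionTable | str],
    membrane_kinds: list[str],
    orientations: list[int],
    base: dict | None = None,
) -> list:
    """Full Cartesian product of scenario factors as ScenarioConfig objects.

    Ordering is deterministic with orientation varying fastest, matching a
    6-orientation x 2-protein x 2-composition x 3-core factorial of 72 systems.
    Extra ScenarioConfig fields can be supplied through ``base``.
    """
    from .synthetic import ScenarioConfig  # deferred to avoid a cycle

    if not (proteins and tables and membrane_kinds and orientations):
        raise ValueError("all factor lists must be non-empty")
    base = dict(base or {})
    configs = []
    for protein in proteins:
        for table in tables:
            for kind in membrane_kinds:
                for orient in orientations:
                    configs.append(
                        ScenarioConfig(
                            membrane_kind=kind,
                            composition=get_table(table).name,
                            orientation_index=orient,
                            protein=protein,
                            **base,
                        )
                    )
    return configs
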