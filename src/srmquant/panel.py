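"""Analyte-panel registry for targeted SRM/MRM quantitation.

A panel couples three things that every downstream stage needs:

* the SRM transitions measured per analyte (one *quantifier* used for
  quantitation, optional *qualifiers* used only for identity confirmation),
* the stable-isotope-labeled internal standard (ISTD) each analyte is
  normalized against, together with its working concentration in the ISTD MIX,
* *co-quantified groups*: chromatographically unresolved isomer pairs that
  share a quantifier transition and are reported as a single concentration
  (e.g. leucine + isoleucine). Members of such a group collapse into one
  "quantification entity" from ingestion onward.

The builtin fixture ``diabetes-t1d-34`` encodes a 34-analyte / 33-ISTD plasma
panel of amino acids, bile acids, and small organic acids used for diabetes
patient stratification. It contains four merged pairs (Leu+Ile, TDCA+TCDCA,
GCDCA+GDCA, ADMA+SDMA → 30 quantification entities) and three analytes
(Crea, GBB, b-OHB) quantified without ISTD normalization because their
labeled-standard signal is not repeatable. Greek letters in analyte names are
romanized in abbreviations (β-OHB → ``b-OHB``, α(R)-OHB → ``aR-OHB``).

Acquisition voltages (fragmentor, collision energy, cell accelerator) are
carried as opaque metadata and play no computational role.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PanelSchemaError",
    "Transition",
    "AnalyteDef",
    "IstdDef",
    "QuantEntity",
    "AnalytePanel",
    "load_panel",
    "write_panel",
    "quantification_entities",
    "BUILTIN_PANELS",
]

POLARITIES = frozenset({"positive", "negative"})
ROLES = frozenset({"quantifier", "qualifier"})
GROUPS = frozenset({"amino_acid_related", "bile_acid", "other", "small_organic_acid"})

#: tolerance for pseudo-fragmentation entries where precursor and product are
#: the identical (unfragmented) deprotonated molecule, e.g. CDCA 391.3→391.3
_PRODUCT_MZ_SLACK = 1.0

BUILTIN_PANELS = {"diabetes-t1d-34"}

ANALYTE_COLUMNS = [
    "abbreviation", "name", "group", "precursor_mz", "product_mz",
    "polarity", "role", "istd_abbreviation", "co_quantified_group",
]
_VOLTAGE_COLUMNS = ["fragmentor_v", "collision_energy_v", "cell_accelerator_v"]
ISTD_COLUMNS = ["abbreviation", "mix_concentration_ng_per_ml"]


class PanelSchemaError(ValueError):
    """Raised when a panel file or object violates the panel schema."""


@dataclass(frozen=True)
class Transition:
    """A single precursor→product SRM ion transition."""

    precursor_mz: float
    product_mz: float
    polarity: str
    role: str
    fragmentor_v: float | None = None
    collision_energy_v: float | None = None
    cell_accelerator_v: float | None = None

    def __post_init__(self) -> None:
        if not (self.precursor_mz > 0 and math.isfinite(self.precursor_mz)):
            raise PanelSchemaError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if not (self.product_mz > 0 and math.isfinite(self.product_mz)):
            raise PanelSchemaError(f"product_mz must be positive, got {self.product_mz}")
        if self.product_mz > self.precursor_mz + _PRODUCT_MZ_SLACK:
            raise PanelSchemaError(
                f"product_mz {self.product_mz} exceeds precursor_mz "
                f"{self.precursor_mz} beyond the pseudo-fragmentation tolerance"
            )
        if self.polarity not in POLARITIES:
            raise PanelSchemaError(f"polarity must be one of {sorted(POLARITIES)}, got {self.polarity!r}")
        if self.role not in ROLES:
            raise PanelSchemaError(f"role must be one of {sorted(ROLES)}, got {self.role!r}")


@dataclass(frozen=True)
class AnalyteDef:
    """One measured analyte with its transitions and ISTD pairing."""

    abbreviation: str
    name: str
    group: str
    transitions: tuple[Transition, ...]
    istd_abbreviation: str | None = None
    co_quantified_group: str | None = None

    def __post_init__(self) -> None:
        if not self.abbreviation:
            raise PanelSchemaError("analyte abbreviation must be non-empty")
        if self.group not in GROUPS:
            raise PanelSchemaError(
                f"analyte {self.abbreviation!r}: group must be one of "
                f"{sorted(GROUPS)}, got {self.group!r}"
            )
        n_quant = sum(t.role == "quantifier" for t in self.transitions)
        if n_quant != 1:
            raise PanelSchemaError(
                f"analyte {self.abbreviation!r} must have exactly one quantifier "
                f"transition, found {n_quant}"
            )

    @property
    def quantifier(self) -> Transition:
        return next(t for t in self.transitions if t.role == "quantifier")


@dataclass(frozen=True)
class IstdDef:
    """An internal standard and its concentration in the ISTD MIX (ng mL^-1)."""

    abbreviation: str
    mix_concentration: float

    def __post_init__(self) -> None:
        if not self.abbreviation:
            raise PanelSchemaError("ISTD abbreviation must be non-empty")
        if not (self.mix_concentration > 0 and math.isfinite(self.mix_concentration)):
            raise PanelSchemaError(
                f"ISTD {self.abbreviation!r}: mix_concentration must be positive"
            )


@dataclass(frozen=True)
class QuantEntity:
    """A quantification entity: a stand-alone analyte or a merged isomer group.

    This is the unit downstream stages operate on — one calibration curve,
    one reported concentration, one (or no) ISTD per entity.
    """

    name: str
    members: tuple[str, ...]
    istd_abbreviation: str | None
    quantifier: Transition

    @property
    def is_merged(self) -> bool:
        return len(self.members) > 1

    @property
    def has_istd(self) -> bool:
        return self.istd_abbreviation is not None


@dataclass
class AnalytePanel:
    """A validated collection of analytes and internal standards."""

    analytes: list[AnalyteDef] = field(default_factory=list)
    istds: list[IstdDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.analytes:
            raise PanelSchemaError("panel contains no analytes")
        seen: set[str] = set()
        for a in self.analytes:
            if a.abbreviation in seen:
                raise PanelSchemaError(f"duplicate analyte abbreviation {a.abbreviation!r}")
            seen.add(a.abbreviation)
        istd_seen: set[str] = set()
        for s in self.istds:
            if s.abbreviation in istd_seen:
                raise PanelSchemaError(f"duplicate ISTD abbreviation {s.abbreviation!r}")
            istd_seen.add(s.abbreviation)
        for a in self.analytes:
            if a.istd_abbreviation is not None and a.istd_abbreviation not in istd_seen:
                raise PanelSchemaError(
                    f"analyte {a.abbreviation!r} references unknown ISTD "
                    f"{a.istd_abbreviation!r}"
                )
        # merged groups: one shared ISTD (or none for all) and one shared quantifier
        groups: dict[str, list[AnalyteDef]] = {}
        for a in self.analytes:
            if a.co_quantified_group:
                groups.setdefault(a.co_quantified_group, []).append(a)
        for gname, members in groups.items():
            istd_set = {m.istd_abbreviation for m in members}
            if len(istd_set) != 1:
                raise PanelSchemaError(
                    f"co-quantified group {gname!r}: members must share one ISTD "
                    f"(or all have none), found {sorted(map(str, istd_set))}"
                )
            quant_mz = {(m.quantifier.precursor_mz, m.quantifier.product_mz) for m in members}
            if len(quant_mz) != 1:
                raise PanelSchemaError(
                    f"co-quantified group {gname!r}: members must share the "
                    f"quantifier transition, found {sorted(quant_mz)}"
                )

    # -- lookups -----------------------------------------------------------

    def analyte(self, abbreviation: str) -> AnalyteDef:
        for a in self.analytes:
            if a.abbreviation == abbreviation:
                return a
        raise KeyError(abbreviation)

    def istd(self, abbreviation: str) -> IstdDef:
        for s in self.istds:
            if s.abbreviation == abbreviation:
                return s
        raise KeyError(abbreviation)

    def istd_mix_concentration(self, abbreviation: str) -> float:
        return self.istd(abbreviation).mix_concentration

    def entities(self) -> list[QuantEntity]:
        return quantification_entities(self)

    def entity(self, name: str) -> QuantEntity:
        for e in self.entities():
            if e.name == name:
                return e
        raise KeyError(name)


def quantification_entities(panel: AnalytePanel) -> list[QuantEntity]:
    """Resolve the panel into quantification entities.

    Stand-alone analytes map one-to-one to entities named by their
    abbreviation; each co-quantified group collapses to a single entity named
    by the group label. The result is sorted by entity name and therefore
    independent of input row order.
    """
    entities: list[QuantEntity] = []
    grouped: dict[str, list[AnalyteDef]] = {}
    for a in panel.analytes:
        if a.co_quantified_group:
            grouped.setdefault(a.co_quantified_group, []).append(a)
        else:
            entities.append(
                QuantEntity(
                    name=a.abbreviation,
                    members=(a.abbreviation,),
                    istd_abbreviation=a.istd_abbreviation,
                    quantifier=a.quantifier,
                )
            )
    for gname, members in grouped.items():
        members = sorted(members, key=lambda m: m.abbreviation)
        entities.append(
            QuantEntity(
                name=gname,
                members=tuple(m.abbreviation for m in members),
                istd_abbreviation=members[0].istd_abbreviation,
                quantifier=members[0].quantifier,
            )
        )
    return sorted(entities, key=lambda e: e.name)


# -- I/O -------------------------------------------------------------------


def _builtin_path(kind: str) -> Path:
    res = importlib.resources.files("srmquant.data")
    return Path(str(res / f"panel_{kind}.csv"))


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", skip_blank_lines=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise PanelSchemaError(f"could not parse {path}: {exc}") from exc


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def load_panel(
    source: str | Path = "diabetes-t1d-34",
    istd_source: str | Path | None = None,
) -> AnalytePanel:
    """Load and validate an analyte panel.

    Parameters
    ----------
    source:
        Either the name of a builtin fixture (``"diabetes-t1d-34"``) or a path
        to an analyte CSV (one row per transition; see module docs for the
        schema).
    istd_source:
        Path to the ISTD CSV. Required when ``source`` is a file path and any
        analyte references an ISTD; ignored for builtin fixtures.
    """
    if isinstance(source, str) and source in BUILTIN_PANELS:
        analyte_df = _read_csv(_builtin_path("analytes"))
        istd_df = _read_csv(_builtin_path("istds"))
    else:
        analyte_df = _read_csv(source)
        istd_df = _read_csv(istd_source) if istd_source is not None else None

    missing = [c for c in ANALYTE_COLUMNS if c not in analyte_df.columns]
    if missing:
        raise PanelSchemaError(f"analyte table is missing columns: {missing}")

    istds: list[IstdDef] = []
    if istd_df is not None:
        missing = [c for c in ISTD_COLUMNS if c not in istd_df.columns]
        if missing:
            raise PanelSchemaError(f"ISTD table is missing columns: {missing}")
        for row in istd_df.itertuples(index=False):
            istds.append(
                IstdDef(
                    abbreviation=str(row.abbreviation),
                    mix_concentration=float(row.mix_concentration_ng_per_ml),
                )
            )

    analytes: list[AnalyteDef] = []
    for abbrev, rows in analyte_df.groupby("abbreviation", sort=False):
        transitions = tuple(
            Transition(
                precursor_mz=float(r.precursor_mz),
                product_mz=float(r.product_mz),
                polarity=str(r.polarity),
                role=str(r.role),
                fragmentor_v=_float_or_none(getattr(r, "fragmentor_v", None)),
                collision_energy_v=_float_or_none(getattr(r, "collision_energy_v", None)),
                cell_accelerator_v=_float_or_none(getattr(r, "cell_accelerator_v", None)),
            )
            for r in rows.itertuples(index=False)
        )
        first = rows.iloc[0]
        istd_ref = {_opt(r) for r in rows["istd_abbreviation"]}
        group_ref = {_opt(r) for r in rows["co_quantified_group"]}
        if len(istd_ref) != 1 or len(group_ref) != 1:
            raise PanelSchemaError(
                f"analyte {abbrev!r}: transition rows disagree on ISTD or group"
            )
        analytes.append(
            AnalyteDef(
                abbreviation=str(abbrev),
                name=str(first["name"]),
                group=str(first["group"]),
                transitions=transitions,
                istd_abbreviation=istd_ref.pop(),
                co_quantified_group=group_ref.pop(),
            )
        )
    return AnalytePanel(analytes=analytes, istds=istds)


def _float_or_none(value) -> float | None:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def write_panel(
    panel: AnalytePanel,
    analyte_path: str | Path,
    istd_path: str | Path | None = None,
) -> None:
    """Serialize a panel back to the delimited schema read by :func:`load_panel`."""
    rows = []
    for a in panel.analytes:
        for t in a.transitions:
            rows.append(
                {
                    "abbreviation": a.abbreviation,
                    "name": a.name,
                    "group": a.group,
                    "precursor_mz": t.precursor_mz,
                    "product_mz": t.product_mz,
                    "polarity": t.polarity,
                    "role": t.role,
                    "istd_abbreviation": a.istd_abbreviation,
                    "co_quantified_group": a.co_quantified_group,
                    "fragmentor_v": t.fragmentor_v,
                    "collision_energy_v": t.collision_energy_v,
                    "cell_accelerator_v": t.cell_accelerator_v,
                }
            )
    pd.DataFrame(rows, columns=ANALYTE_COLUMNS + _VOLTAGE_COLUMNS).to_csv(
        analyte_path, index=False
    )
    if istd_path is not None:
        pd.DataFrame(
            [
                {
                    "abbreviation": s.abbreviation,
                    "mix_concentration_ng_per_ml": s.mix_concentration,
                }
                for s in panel.istds
            ],
            columns=ISTD_COLUMNS,
        ).to_csv(istd_path, index=False)
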