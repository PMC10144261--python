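"""Tabular I/O: the PSM CSV schema, variant-call naming, and triage config.

Search-engine exports vary wildly; everything downstream of this module
consumes one neutral, diff-able CSV schema instead.  A row is one
peptide-spectrum match (PSM) with its location on the protein, charge,
observed/theoretical m/z, precursor mass error in ppm, engine score, XIC
area, modifications, and an optional sequence-variant call written in the
field's canonical ``{wt}{position}{obs}_{chain}`` form (e.g. ``D1E_LC``).

Reads are validating: the stated precursor ppm is recomputed from the two
m/z values and must agree to 1e-3 ppm, so silently inconsistent exports are
rejected at the door.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .chem import (
    DEFAULT_TABLE,
    ModificationDef,
    ResidueMassTable,
    substitution_delta,
)
from .digestion import DEFAULT_ENZYMES, EnzymeSpec

_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Za-z]+|[+-]\d+(?:\.\d+)?)(?:_(.+))?$")


@dataclass(frozen=True)
class VariantCall:
    """A single amino-acid substitution call.

    ``observed`` is either a residue symbol (possibly multi-letter, e.g.
    ``Mnl``) or a signed delta string like ``+58.0055`` for delta-only calls.
    """

    protein_id: str
    position: int  # 1-based on the protein chain
    wildtype: str
    observed: str
    chain_label: str = ""

    @property
    def name(self) -> str:
        chain = f"_{self.chain_label}" if self.chain_label else ""
        return f"{self.wildtype}{self.position}{self.observed}{chain}"

    @property
    def site(self) -> tuple[str, int, str]:
        """Variant-site key used for cross-enzyme grouping."""
        return (self.protein_id, self.position, self.observed)

    @property
    def is_delta_only(self) -> bool:
        return self.observed[0] in "+-"

    def delta(self, table: ResidueMassTable = DEFAULT_TABLE) -> float:
        """Mass shift of the substitution in Da."""
        if self.is_delta_only:
            return float(self.observed)
        return substitution_delta(self.wildtype, self.observed, table)

    @classmethod
    def from_name(cls, name: str, protein_id: str) -> "VariantCall":
        m = _VARIANT_RE.match(name)
        if not m:
            raise ValueError(f"unparsable variant name {name!r}")
        wt, pos, obs, chain = m.groups()
        return cls(protein_id, int(pos), wt, obs, chain or "")


@dataclass
class PSMRecord:
    """One peptide-spectrum match as exported by a search engine."""

    psm_id: str
    peptide: str
    protein_id: str
    start: int
    end: int
    enzyme: str
    charge: int
    mz_observed: float
    mz_theoretical: float
    precursor_ppm: float
    score: float
    engine: str
    rt: float
    xic_area: float
    mods: tuple[tuple[int, str], ...] = ()
    variant: VariantCall | None = None

    def validate(self) -> None:
        if self.charge < 1:
            raise ValueError(f"PSM {self.psm_id}: charge must be >= 1")
        if self.xic_area < 0:
            raise ValueError(f"PSM {self.psm_id}: xic_area must be >= 0")
        recomputed = 1e6 * (self.mz_observed - self.mz_theoretical) / self.mz_theoretical
        if abs(recomputed - self.precursor_ppm) > 1e-3:
            raise ValueError(
                f"PSM {self.psm_id}: stated precursor_ppm {self.precursor_ppm} "
                f"inconsistent with m/z values (recomputed {recomputed:.4f})")


PSM_COLUMNS = [
    "psm_id", "peptide", "protein_id", "start", "end", "enzyme", "charge",
    "mz_observed", "mz_theoretical", "precursor_ppm", "score", "engine",
    "rt", "xic_area", "mods", "variant",
]


def _fmt_mods(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


def _parse_mods(text: str) -> tuple[tuple[int, str], ...]:
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        pos, name = item.split(":", 1)
        out.append((int(pos), name))
    return tuple(out)


def read_psm_table(path: str | Path) -> list[PSMRecord]:
    """Read and validate a PSM CSV; errors carry the offending row index."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in PSM_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"PSM table {path} missing column(s): {missing}")
        records = []
        for idx, row in enumerate(reader, start=1):
            try:
                variant = None
                if row["variant"]:
                    variant = VariantCall.from_name(row["variant"], row["protein_id"])
                rec = PSMRecord(
                    psm_id=row["psm_id"] or f"row{idx}",
                    peptide=row["peptide"],
                    protein_id=row["protein_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    enzyme=row["enzyme"],
                    charge=int(row["charge"]),
                    mz_observed=float(row["mz_observed"]),
                    mz_theoretical=float(row["mz_theoretical"]),
                    precursor_ppm=float(row["precursor_ppm"]),
                    score=float(row["score"]),
                    engine=row["engine"],
                    rt=float(row["rt"]),
                    xic_area=float(row["xic_area"]),
                    mods=_parse_mods(row["mods"]),
                    variant=variant,
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"PSM table {path} row {idx}: {exc}") from exc
            rec.validate()
            records.append(rec)
    return records


def write_psm_table(records: Iterable[PSMRecord], path: str | Path,
                    extra_columns: dict[str, dict[str, str]] | None = None) -> None:
    """Write records as CSV.

    Floats use shortest round-trip repr so read∘write is field-identical.
    ``extra_columns`` maps column name -> {psm_id: value} for annotation
    outputs (status, triggered rules, comment).
    """
    extra = extra_columns or {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PSM_COLUMNS + list(extra))
        for rec in records:
            row = [
                rec.psm_id, rec.peptide, rec.protein_id, rec.start, rec.end,
                rec.enzyme, rec.charge, repr(rec.mz_observed),
                repr(rec.mz_theoretical), repr(rec.precursor_ppm),
                repr(rec.score), rec.engine, repr(rec.rt), repr(rec.xic_area),
                _fmt_mods(rec.mods),
                rec.variant.name if rec.variant else "",
            ]
            row += [extra[col].get(rec.psm_id, "") for col in extra]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Triage configuration

#: Built-in parameter profiles.  ``high_res`` reflects an internally
#: calibrated Orbitrap workflow (score cutoff 225, 2 ppm MS1 / 5 ppm MS2
#: tolerances, 10 ppm XIC window); ``legacy`` reflects an ion-trap MS2
#: workflow (Mascot-style cutoff 15, ±8 ppm precursor, 0.8 Da fragment
#: tolerance).
PROFILES: dict[str, dict] = {
    "high_res": dict(score_cutoff=225.0, ms1_tol_ppm=2.0, ms2_tol=5.0,
                     ms2_tol_unit="ppm", xic_window_ppm=10.0),
    "legacy": dict(score_cutoff=15.0, ms1_tol_ppm=8.0, ms2_tol=0.8,
                   ms2_tol_unit="Da", xic_window_ppm=10.0),
}


@dataclass
class TriageConfig:
    """Score, tolerance and rule parameters for variant triage."""

    profile: str = "high_res"
    score_cutoff: float = 225.0
    ms1_tol_ppm: float = 2.0
    ms2_tol: float = 5.0
    ms2_tol_unit: str = "ppm"
    xic_window_ppm: float = 10.0
    quant_limit_pct: float = 0.2
    near_terminus_window: int = 2
    residue_match_tol_da: float = 0.005
    terminal_rule_both_signs: bool = False
    enzymes: dict[str, EnzymeSpec] = field(
        default_factory=lambda: dict(DEFAULT_ENZYMES))
    modifications: tuple[ModificationDef, ...] = ()

    def __post_init__(self):
        for name in ("ms1_tol_ppm", "ms2_tol", "xic_window_ppm",
                     "residue_match_tol_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.quant_limit_pct < 0:
            raise ValueError("quant_limit_pct must be >= 0")


_CONFIG_KEYS = {
    "score_cutoff", "ms1_tol_ppm", "ms2_tol", "ms2_tol_unit",
    "xic_window_ppm", "quant_limit_pct", "near_terminus_window",
    "residue_match_tol_da", "terminal_rule_both_signs",
}


def make_config(profile: str = "high_res", **overrides) -> TriageConfig:
    """Build a TriageConfig from a profile plus explicit overrides."""
    if profile not in PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}")
    params = dict(PROFILES[profile])
    unknown = set(overrides) - _CONFIG_KEYS - {"enzymes", "modifications"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    params.update(overrides)
    return TriageConfig(profile=profile, **params)


def _parse_enzyme(name: str, spec: dict) -> EnzymeSpec:
    base = DEFAULT_ENZYMES.get(name)
    kwargs = dict(
        name=name,
        cut_side=spec.get("cut_side", base.cut_side if base else "C"),
        residues=frozenset(spec.get("residues", base.residues if base else ())),
        suppress_before_proline=spec.get(
            "suppress_before_proline",
            base.suppress_before_proline if base else False),
        max_missed_cleavages=spec.get(
            "max_missed_cleavages",
            base.max_missed_cleavages if base else 2),
        min_length=spec.get("min_length", base.min_length if base else 1),
        max_length=spec.get("max_length", base.max_length if base else 50),
    )
    return EnzymeSpec(**kwargs)


def _parse_modification(spec: dict) -> ModificationDef:
    mod = ModificationDef(
        name=spec["name"],
        delta=float(spec["delta"]),
        targets=frozenset(spec.get("targets", ())),
    )
    n_13c = int(spec.get("n_13c", 0))
    if n_13c:
        mod = mod.as_heavy(n_13c)
    return mod


def read_config(path: str | Path | None = None, **overrides) -> TriageConfig:
    """Load a YAML triage config; unspecified keys take profile defaults."""
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config {path} is not a key-value document")
    doc.update(overrides)
    profile = doc.pop("profile", "high_res")
    enzymes = doc.pop("enzymes", None)
    modifications = doc.pop("modifications", None)
    cfg = make_config(profile, **doc)
    if enzymes:
        registry = dict(DEFAULT_ENZYMES)
        for name, spec in enzymes.items():
            registry[name] = _parse_enzyme(name, spec or {})
        cfg = replace(cfg, enzymes=registry)
    if modifications:
        cfg = replace(cfg, modifications=tuple(
            _parse_modification(m) for m in modifications))
    return cfg
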