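"""Synthetic peptide-map projects and a phenomenological DDA acquisition model.

Two generators live here:

* :func:`simulate_acquisition` — a minimal Orbitrap-style MS1 acquisition
  model with Poisson ion statistics and an injection-time-gating feature.
  The instrument reports intensity as detected ions divided by the actual
  fill time; when a space-charge proxy exceeds a ppm threshold the fill time
  is slashed and the dominant species' reported signal is inflated by a
  configurable gain (~2x), under-quantitating co-eluting low-level species.
  Raising the threshold to 100 ppm disables the feature and restores an
  unbiased estimator.
* :func:`synth_project` — a seeded spiked-variant peptide map: a two-chain
  protein, its digest peptides as wildtype PSMs, planted true sequence
  variants at fractional-percent levels, and planted false positives of the
  four triage classes, with a truth table recording every plant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import chem
from .chem import DEFAULT_TABLE
from .digestion import (
    ASP_N,
    THERMOLYSIN,
    TRYPSIN,
    PeptideMatch,
    ProteinRecord,
    classify_specificity,
    digest,
    write_fasta,
)
from .psm_io import PSMRecord, VariantCall, write_psm_table
from .quant import relative_quant

# ---------------------------------------------------------------------------
# Acquisition model


@dataclass
class AcquisitionConfig:
    """Duty-cycle, trap-fill and gating parameters of the acquisition model.

    ``iit_threshold_ppm`` is the space-charge proxy threshold: 0.75 ppm is
    the aggressive factory default; 100 ppm effectively disables gating.
    ``gating_factor`` divides the fill time in a gated scan and
    ``dominant_gain`` multiplies the reported intensity of species holding
    at least ``dominance_fraction`` of the detected ions there.
    """

    mode: str = "MS1_only"  # "MS1_only" | "DDA"
    top_n: int = 5
    ms1_scan_s: float = 0.25
    ms2_scan_s: float = 0.15
    max_inject_ms: float = 120.0
    agc_target: float = 4e5
    iit_threshold_ppm: float = 0.75
    gating_factor: float = 10.0
    dominant_gain: float = 2.0
    dominance_fraction: float = 0.3
    spacecharge_coeff: float = 5.0  # ppm per unit trap-fill fraction
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("MS1_only", "DDA"):
            raise ValueError("mode must be 'MS1_only' or 'DDA'")
        if self.mode == "DDA" and self.top_n < 1:
            raise ValueError("top_n must be >= 1 in DDA mode")
        for name in ("ms1_scan_s", "ms2_scan_s", "max_inject_ms", "agc_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gating_factor <= 1:
            raise ValueError("gating_factor must be > 1")
        if self.dominant_gain < 1:
            raise ValueError("dominant_gain must be >= 1")
        if not 0 < self.dominance_fraction <= 1:
            raise ValueError("dominance_fraction must be in (0, 1]")

    @property
    def cycle_s(self) -> float:
        """MS1 cadence: one duty cycle."""
        if self.mode == "DDA":
            return self.ms1_scan_s + self.top_n * self.ms2_scan_s
        return self.ms1_scan_s


@dataclass(frozen=True)
class SimSpecies:
    """One Gaussian-eluting precursor."""

    id: str
    mz: float
    charge: int
    elution_center_s: float
    elution_sigma_s: float
    apex_flux: float  # ions per second at the elution apex

    def __post_init__(self):
        if self.apex_flux < 0:
            raise ValueError("apex_flux must be >= 0")
        if self.elution_sigma_s <= 0:
            raise ValueError("elution_sigma_s must be positive")

    def flux(self, time_s: float) -> float:
        x = (time_s - self.elution_center_s) / self.elution_sigma_s
        return self.apex_flux * math.exp(-0.5 * x * x)


@dataclass(frozen=True)
class ScanRecord:
    """One MS1 scan: actual fill time, gating flag, reported intensities."""

    time_s: float
    t_actual_ms: float
    gated: bool
    intensities: Mapping[str, float]


def scan_schedule(cfg: AcquisitionConfig, run_length_s: float) -> np.ndarray:
    """Deterministic MS1 scan start times over the run."""
    cycle = cfg.cycle_s
    if run_length_s <= cycle:
        raise ValueError("run length must exceed one duty cycle")
    return np.arange(0.0, run_length_s, cycle)


def scans_per_peak(cfg: AcquisitionConfig, elution_sigma_s: float) -> int:
    """Guaranteed MS1 scans inside a ±2σ peak window at the schedule cadence."""
    return int(math.floor(4.0 * elution_sigma_s / cfg.cycle_s))


def check_scans_per_peak(
    cfg: AcquisitionConfig, elution_sigma_s: float, minimum: int = 8
) -> bool:
    """Design check: at least ``minimum`` MS1 scans per peak; warns if not."""
    n = scans_per_peak(cfg, elution_sigma_s)
    if n < minimum:
        warnings.warn(
            f"only {n} MS1 scans per +/-2-sigma peak at cycle "
            f"{cfg.cycle_s:.3g} s (minimum {minimum}); XIC quantitation will "
            "be degraded", stacklevel=2)
        return False
    return True


def simulate_acquisition(
    species: Sequence[SimSpecies],
    cfg: AcquisitionConfig,
    run_length_s: float,
    rng: np.random.Generator | None = None,
) -> list[ScanRecord]:
    """Simulate MS1 scans over the run; seeded and reproducible.

    Per scan: the nominal fill time is ``min(max_inject, AGC/total_flux)``;
    the space-charge proxy is ``spacecharge_coeff`` times the trap-fill
    fraction; in DDA mode, when the proxy exceeds the IIT threshold the
    actual fill time is divided by ``gating_factor``.  Detected ions are
    Poisson draws at ``flux x fill time``; reported intensity is ions per
    second, with dominant species inflated by ``dominant_gain`` in gated
    scans.
    """
    if not species:
        raise ValueError("at least one species is required")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    max_inject_s = cfg.max_inject_ms / 1000.0
    records = []
    for t in scan_schedule(cfg, run_length_s):
        fluxes = np.array([sp.flux(t) for sp in species])
        total = float(fluxes.sum())
        t_nom = max_inject_s if total == 0 else min(
            max_inject_s, cfg.agc_target / total)
        fill_fraction = total * t_nom / cfg.agc_target
        shift_ppm = cfg.spacecharge_coeff * fill_fraction
        gated = cfg.mode == "DDA" and shift_ppm > cfg.iit_threshold_ppm
        t_act = t_nom / cfg.gating_factor if gated else t_nom
        counts = rng.poisson(fluxes * t_act)
        total_counts = counts.sum()
        intensities = {}
        for sp, n in zip(species, counts):
            intensity = n / t_act
            if (gated and total_counts > 0
                    and n / total_counts >= cfg.dominance_fraction):
                intensity *= cfg.dominant_gain
            intensities[sp.id] = float(intensity)
        records.append(ScanRecord(float(t), t_act * 1000.0, gated, intensities))
    return records


def xic_and_quant(
    scans: Sequence[ScanRecord], variant_id: str, wildtype_id: str
) -> float:
    """Trapezoidal XIC areas over MS1 scans, then relative quantitation (%)."""
    times = np.array([s.time_s for s in scans])
    traces = {}
    for sid in (variant_id, wildtype_id):
        trace = np.array([s.intensities[sid] for s in scans])
        if np.count_nonzero(trace) < 3:
            raise ValueError(
                f"fewer than 3 MS1 scans carry signal for {sid!r}; "
                "cannot integrate an XIC peak")
        traces[sid] = trace
    area_v = float(np.trapezoid(traces[variant_id], times))
    area_w = float(np.trapezoid(traces[wildtype_id], times))
    return relative_quant(area_v, area_w)


def make_spike_pair(
    level_pct: float,
    total_apex_flux: float = 1e6,
    center_s: float = 30.0,
    sigma_s: float = 2.0,
) -> tuple[SimSpecies, SimSpecies]:
    """Co-eluting (minor, major) species pair at the given spike level (%)."""
    if not 0 < level_pct < 100:
        raise ValueError("level_pct must be in (0, 100)")
    minor_flux = total_apex_flux * level_pct / 100.0
    minor = SimSpecies("variant", 500.25, 2, center_s, sigma_s, minor_flux)
    major = SimSpecies("wildtype", 501.25, 2, center_s, sigma_s,
                       total_apex_flux - minor_flux)
    return minor, major


def estimate_spike_recovery(
    level_pct: float,
    cfg: AcquisitionConfig,
    seed: int | None = None,
    total_apex_flux: float = 1e6,
    center_s: float = 30.0,
    sigma_s: float = 2.0,
    run_length_s: float = 60.0,
) -> float:
    """End-to-end spike recovery: simulate, integrate XICs, quantify (%)."""
    minor, major = make_spike_pair(level_pct, total_apex_flux, center_s, sigma_s)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    scans = simulate_acquisition([minor, major], cfg, run_length_s, rng)
    return xic_and_quant(scans, minor.id, major.id)


# ---------------------------------------------------------------------------
# Synthetic spiked-variant peptide-map projects

#: Residue sampling weights for synthetic chains: ~10% K/R (tryptic site
#: density of a typical mAb) with small residues enriched.
_RESIDUE_WEIGHTS = {
    "K": 0.05, "R": 0.05, "G": 0.12, "A": 0.12, "S": 0.07, "T": 0.07,
    "V": 0.07, "L": 0.07, "D": 0.06, "E": 0.06, "N": 0.04, "Q": 0.04,
    "F": 0.04, "I": 0.04, "P": 0.02, "Y": 0.03, "H": 0.02, "M": 0.01,
    "W": 0.01, "C": 0.01,
}


@dataclass
class SynthProjectConfig:
    """Study design of a synthetic spiked-variant project.

    Defaults are the ``sva7`` fixture: seven true sequence variants spiked
    at 0.2% with best tryptic scores >= 225 of which exactly three fall in
    [225, 250), plus fifty planted false positives (20 semi-tryptic
    non-K/R, 10 terminal-residue, 10 below-limit, 10 orthogonal-redundant).
    """

    chains: tuple[tuple[str, int], ...] = (("HC", 450), ("LC", 214))
    protein_stem: str = "synmab1"
    n_true_sv: int = 7
    true_sv_level_pct: float = 0.2
    n_true_mid_score: int = 3
    mid_score_range: tuple[float, float] = (226.0, 249.0)
    high_score_range: tuple[float, float] = (260.0, 420.0)
    n_fp_semi: int = 20
    n_fp_terminal: int = 10
    n_fp_sublimit: int = 10
    n_fp_orthogonal: int = 10
    fp_level_pct: float = 0.5
    sublimit_level_range: tuple[float, float] = (0.05, 0.15)
    fp_score_range: tuple[float, float] = (260.0, 420.0)
    ortho_score_range: tuple[float, float] = (226.0, 248.0)
    n_ppm_decoys: int = 0
    decoy_ppm_range: tuple[float, float] = (3.0, 7.0)
    wildtype_area: float = 1e6
    area_log_sigma: float = 0.3
    ppm_sigma: float = 0.5
    ppm_clip: float = 1.5
    residue_match_tol_da: float = 0.005


@dataclass
class SynthProject:
    """Generated project: proteins, PSM table, and the planting truth."""

    proteins: list[ProteinRecord]
    psms: list[PSMRecord]
    truth: list[dict]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "project.fasta",
            "psms": out / "psms.csv",
            "truth": out / "truth.csv",
        }
        write_fasta(self.proteins, paths["fasta"])
        write_psm_table(self.psms, paths["psms"])
        import csv as _csv
        with open(paths["truth"], "w", newline="") as fh:
            writer = _csv.DictWriter(fh, fieldnames=[
                "variant_name", "protein_id", "position", "wildtype",
                "observed", "klass", "level_pct", "expected_rule", "psm_ids"])
            writer.writeheader()
            for row in self.truth:
                writer.writerow(row)
        return paths

    @property
    def true_sites(self) -> set[tuple[str, int, str]]:
        return {(r["protein_id"], r["position"], r["observed"])
                for r in self.truth if r["klass"] == "true_sv"}


def _make_chain(rng: np.random.Generator, length: int) -> str:
    symbols = sorted(_RESIDUE_WEIGHTS)
    probs = np.array([_RESIDUE_WEIGHTS[s] for s in symbols])
    probs = probs / probs.sum()
    return "".join(rng.choice(symbols, size=length, p=probs))


def _residue_mass_matches(delta: float, tol: float) -> list[str]:
    return [sym for sym in DEFAULT_TABLE.canonical_symbols
            if abs(delta - DEFAULT_TABLE.mass(sym)) <= tol]


def _safe_observed(wildtype: str, tol: float) -> list[str]:
    """Substitution targets whose delta cannot trip the terminal-residue rule."""
    out = []
    for obs in DEFAULT_TABLE.canonical_symbols:
        if obs == wildtype or obs in ("K", "R"):
            continue
        delta = chem.substitution_delta(wildtype, obs)
        if abs(delta) < 0.02:
            continue  # I<->L style invisible swaps
        if _residue_mass_matches(delta, tol + 0.002):
            continue
        out.append(obs)
    return out


def _terminal_observed(wildtype: str, tol: float) -> list[tuple[str, str]]:
    """(observed, matched residue) pairs whose delta equals a residue mass."""
    out = []
    for obs in DEFAULT_TABLE.canonical_symbols:
        if obs == wildtype or obs in ("K", "R"):
            continue
        delta = chem.substitution_delta(wildtype, obs)
        for sym in _residue_mass_matches(delta, tol - 0.001):
            out.append((obs, sym))
    return out


class _ProjectBuilder:
    def __init__(self, cfg: SynthProjectConfig, seed: int):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.psms: list[PSMRecord] = []
        self.truth: list[dict] = []
        self._wt_by_span: dict[tuple[str, int, int, str], PSMRecord] = {}
        self._used_positions: set[tuple[str, int]] = set()
        self._next_id = 1
        self.proteins = [
            ProteinRecord(f"{cfg.protein_stem}_{label}", label,
                          _make_chain(self.rng, length))
            for label, length in cfg.chains
        ]
        self.by_id = {p.id: p for p in self.proteins}
        self.tryptic = {p.id: digest(p, TRYPSIN) for p in self.proteins}

    # -- low-level emitters -------------------------------------------------

    def _psm_id(self) -> str:
        pid = f"p{self._next_id:05d}"
        self._next_id += 1
        return pid

    def _draw_ppm(self) -> float:
        c = self.cfg
        return float(np.clip(self.rng.normal(0.0, c.ppm_sigma),
                             -c.ppm_clip, c.ppm_clip))

    def _emit(self, peptide: str, protein_id: str, start: int, end: int,
              enzyme: str, score: float, area: float,
              variant: VariantCall | None, ppm: float | None = None) -> PSMRecord:
        charge = 2 if len(peptide) <= 15 else 3
        mass = chem.peptide_mass(peptide)
        mz_theo = chem.mz_from_mass(mass, charge)
        if ppm is None:
            ppm = self._draw_ppm()
        mz_obs = mz_theo * (1.0 + ppm / 1e6)
        rec = PSMRecord(
            psm_id=self._psm_id(), peptide=peptide, protein_id=protein_id,
            start=start, end=end, enzyme=enzyme, charge=charge,
            mz_observed=mz_obs, mz_theoretical=mz_theo,
            precursor_ppm=1e6 * (mz_obs - mz_theo) / mz_theo,
            score=float(score), engine="byonic-like",
            rt=float(round(self.rng.uniform(5.0, 90.0), 2)),
            xic_area=float(area), variant=variant)
        self.psms.append(rec)
        return rec

    def _ensure_wildtype(self, protein_id: str, start: int, end: int,
                         enzyme: str) -> PSMRecord:
        key = (protein_id, start, end, enzyme)
        if key not in self._wt_by_span:
            c = self.cfg
            peptide = self.by_id[protein_id].sequence[start - 1:end]
            area = c.wildtype_area * math.exp(
                self.rng.normal(0.0, c.area_log_sigma))
            score = float(self.rng.uniform(*c.fp_score_range))
            self._wt_by_span[key] = self._emit(
                peptide, protein_id, start, end, enzyme, score, area, None)
        return self._wt_by_span[key]

    def _plant(self, protein_id: str, start: int, end: int, enzyme: str,
               position: int, observed: str, level_pct: float,
               scores: Sequence[float], klass: str, expected_rule: str,
               ppm: float | None = None) -> None:
        protein = self.by_id[protein_id]
        wildtype = protein.sequence[position - 1]
        wt_psm = self._ensure_wildtype(protein_id, start, end, enzyme)
        total_v = wt_psm.xic_area * level_pct / (100.0 - level_pct)
        weights = self.rng.uniform(0.8, 1.2, size=len(scores))
        weights = weights / weights.sum()
        pep = protein.sequence[start - 1:end]
        idx = position - start
        var_pep = pep[:idx] + observed + pep[idx + 1:]
        call = VariantCall(protein_id, position, wildtype, observed,
                           protein.chain_label)
        ids = []
        for score, w in zip(scores, weights):
            rec = self._emit(var_pep, protein_id, start, end, enzyme,
                             score, total_v * w, call, ppm=ppm)
            ids.append(rec.psm_id)
        self.truth.append(dict(
            variant_name=call.name, protein_id=protein_id, position=position,
            wildtype=wildtype, observed=observed, klass=klass,
            level_pct=level_pct, expected_rule=expected_rule,
            psm_ids=";".join(ids)))
        self._used_positions.add((protein_id, position))

    # -- slot discovery -----------------------------------------------------

    def _slots(self, min_len: int = 5, max_len: int = 30):
        """Shuffled (peptide, interior position) planting slots."""
        slots = []
        for p in self.proteins:
            for m in self.tryptic[p.id]:
                if m.n_missed != 0 or not min_len <= len(m.sequence) <= max_len:
                    continue
                for rel in range(3, len(m.sequence) - 1):  # keep 2 from ends
                    pos = m.start + rel - 1
                    wt = m.sequence[rel - 1]
                    if wt in ("K", "R"):
                        continue
                    slots.append((m, pos, wt))
        order = self.rng.permutation(len(slots))
        return [slots[i] for i in order]

    def _take_slot(self, slots, predicate):
        for i, slot in enumerate(slots):
            m, pos, wt = slot
            if (m.protein_id, pos) in self._used_positions:
                continue
            extra = predicate(slot)
            if extra is not None:
                del slots[i]
                return slot, extra
        raise ValueError(
            "synthetic project config infeasible: not enough planting slots "
            "(increase chain lengths or reduce planted counts)")


def synth_project(
    cfg: SynthProjectConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SynthProject:
    """Generate a seeded spiked-variant project (optionally written to disk)."""
    cfg = cfg or SynthProjectConfig()
    b = _ProjectBuilder(cfg, seed)
    rng = b.rng
    tol = cfg.residue_match_tol_da

    # Baseline wildtype PSMs: every 0-missed tryptic peptide of useful length.
    for p in b.proteins:
        for m in b.tryptic[p.id]:
            if m.n_missed == 0 and 4 <= len(m.sequence) <= 40:
                b._ensure_wildtype(p.id, m.start, m.end, m.enzyme)

    slots = b._slots()

    def pick(options):
        return options[int(rng.integers(len(options)))] if options else None

    def safe_pick(slot):
        return pick(_safe_observed(slot[2], tol))

    # True sequence variants: safe substitutions on full tryptic peptides.
    true_plants = []
    for i in range(cfg.n_true_sv):
        (m, pos, wt), obs = b._take_slot(slots, safe_pick)
        score_range = (cfg.mid_score_range if i < cfg.n_true_mid_score
                       else cfg.high_score_range)
        scores = sorted(rng.uniform(*score_range, size=2), reverse=True)
        b._plant(m.protein_id, m.start, m.end, m.enzyme, pos, obs,
                 cfg.true_sv_level_pct, scores, "true_sv", "")
        true_plants.append(b.truth[-1])

    # Class a: semi-tryptic peptides with an uninvolved variant.
    for _ in range(cfg.n_fp_semi):
        def semi_ok(slot):
            m, pos, wt = slot
            if len(m.sequence) < 6 or pos < m.start + 3:
                return None
            protein = b.by_id[m.protein_id]
            if classify_specificity(m.start + 1, m.end, protein,
                                    TRYPSIN) != "semi":
                return None
            return pick(_safe_observed(wt, tol))
        (m, pos, wt), obs = b._take_slot(slots, semi_ok)
        score = rng.uniform(*cfg.fp_score_range)
        b._plant(m.protein_id, m.start + 1, m.end, m.enzyme, pos, obs,
                 cfg.fp_level_pct, [score], "fp_semi_nonKR", "R1_semi_nonKR")

    # Class b: delta equal to a residue mass present near a peptide terminus.
    for _ in range(cfg.n_fp_terminal):
        def terminal_ok(slot):
            m, pos, wt = slot
            terminal = set(m.sequence[:2] + m.sequence[-2:])
            return pick([(obs, sym) for obs, sym in _terminal_observed(wt, tol)
                         if sym in terminal])
        (m, pos, wt), (obs, _sym) = b._take_slot(slots, terminal_ok)
        score = rng.uniform(*cfg.fp_score_range)
        b._plant(m.protein_id, m.start, m.end, m.enzyme, pos, obs,
                 cfg.fp_level_pct, [score], "fp_terminal_residue",
                 "R2_terminal_residue")

    # Class c: true-looking variants below the quantification limit.
    for _ in range(cfg.n_fp_sublimit):
        (m, pos, wt), obs = b._take_slot(slots, safe_pick)
        level = float(rng.uniform(*cfg.sublimit_level_range))
        score = rng.uniform(*cfg.fp_score_range)
        b._plant(m.protein_id, m.start, m.end, m.enzyme, pos, obs,
                 level, [score], "fp_below_limit", "R3_below_quant_limit")

    # Class d: orthogonal-digest duplicates of the (tryptic) true SV sites.
    ortho_digests = {}
    for p in b.proteins:
        ortho_digests[("asp-n", p.id)] = digest(p, ASP_N)
        ortho_digests[("thermolysin", p.id)] = digest(p, THERMOLYSIN)
    options = []
    for t in true_plants:
        pos = t["position"]
        for enz in ("asp-n", "thermolysin"):
            covering = [m for m in ortho_digests[(enz, t["protein_id"])]
                        if 4 <= len(m.sequence) <= 30
                        and m.start + 1 <= pos <= m.end - 1]
            covering.sort(key=lambda m: (m.end - m.start, m.start))
            options.extend((t, m) for m in covering[:3])
    options.sort(key=lambda o: (o[1].enzyme, o[0]["variant_name"],
                                o[1].start, o[1].end))
    planted_d = 0
    seen_spans = set()
    for t, m in options:
        if planted_d >= cfg.n_fp_orthogonal:
            break
        span = (m.protein_id, m.start, m.end, m.enzyme, t["position"])
        if span in seen_spans:
            continue
        seen_spans.add(span)
        score = rng.uniform(*cfg.ortho_score_range)
        b._used_positions.discard((t["protein_id"], t["position"]))
        b._plant(m.protein_id, m.start, m.end, m.enzyme, t["position"],
                 t["observed"], cfg.true_sv_level_pct, [score],
                 "fp_orthogonal", "R4_orthogonal_redundant")
        planted_d += 1
    if planted_d < cfg.n_fp_orthogonal:
        raise ValueError(
            "synthetic project config infeasible: could not place all "
            "orthogonal-duplicate false positives")

    # Optional high-mass-error decoys (outside 2 ppm, inside 8 ppm).
    for _ in range(cfg.n_ppm_decoys):
        (m, pos, wt), obs = b._take_slot(slots, safe_pick)
        score = rng.uniform(*cfg.fp_score_range)
        ppm = float(rng.uniform(*cfg.decoy_ppm_range) *
                    rng.choice([-1.0, 1.0]))
        b._plant(m.protein_id, m.start, m.end, m.enzyme, pos, obs,
                 cfg.fp_level_pct, [score], "ppm_decoy", "G_mass_error",
                 ppm=ppm)

    project = SynthProject(b.proteins, b.psms, b.truth)
    if out_dir is not None:
        project.write(out_dir)
    return project
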