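"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be simulated here: Poisson colony
counts under a linear-quadratic dose response with gene-specific
radiosensitization (a multiplier on alpha), multiplicative lognormal plate
effects on plating efficiency, non-targeting and strong positive-control
wells, replicate screen runs sharing one true-effect table, two-generation
branching lineage logs, and Poisson metaphase aberration counts.

Determinism contract: identical configuration and seed give bit-identical
output tables.  A ``noise_free`` switch replaces random counts by their
rounded expectations so closed-form checks hold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .survival import lq_survival

_WELLS_PER_ROW = 24  # 384-well geometry


def _well_id(pos: int) -> str:
    return f"{chr(ord('A') + pos // _WELLS_PER_ROW)}{pos % _WELLS_PER_ROW + 1:02d}"


@dataclass
class ScreenSimConfig:
    """Design constants of a simulated radiosensitivity screen.

    Defaults mirror the screen design this emulates where stated (single
    7 Gy screening dose, pooled siRNAs, NT negative and PRKDC-like positive
    controls, triplicate confirmation runs); per-well cell numbers, plating
    efficiency and the HeLa LQ parameters are not published for the screen
    and are invented defaults (see docs/methods.md).
    """

    n_genes: int = 384
    wells_per_plate: int = 80           # gene wells per plate
    nt_wells_per_plate: int = 8
    pos_ctrl_wells_per_plate: int = 4
    n_plates: int | None = None         # derived from n_genes when None
    cells_plated: int = 2000
    base_pe: float = 0.5
    dose: float = 7.0
    alpha0: float = 0.25                # Gy^-1
    beta0: float = 0.03                 # Gy^-2
    effect_model: str = "alpha_multiplier"
    hit_fraction: float = 0.05
    hit_effect_range: tuple = (1.6, 3.0)
    pos_ctrl_multiplier: float = 2.5
    plate_effect_sd: float = 0.1        # lognormal sd of PE plate effect
    n_replicate_runs: int = 1
    noise_free: bool = False
    dispersion: float | None = None     # None = Poisson; >0 = gamma-Poisson (NB)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "wells_per_plate", "nt_wells_per_plate",
                     "pos_ctrl_wells_per_plate", "cells_plated", "n_replicate_runs"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.base_pe <= 1:
            raise ValueError("base_pe must lie in (0, 1]")
        if self.alpha0 < 0 or self.beta0 < 0:
            raise ValueError("alpha0 and beta0 must be >= 0")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if not 0 <= self.hit_fraction <= 1:
            raise ValueError("hit_fraction must lie in [0, 1]")
        lo, hi = self.hit_effect_range
        if lo < 1 or hi < lo:
            raise ValueError("hit_effect_range must satisfy 1 <= lo <= hi")
        if self.pos_ctrl_multiplier < 1:
            raise ValueError("pos_ctrl_multiplier must be >= 1")
        if self.plate_effect_sd < 0:
            raise ValueError("plate_effect_sd must be >= 0")
        if self.effect_model != "alpha_multiplier":
            raise ValueError("effect_model must be 'alpha_multiplier'")
        needed = math.ceil(self.n_genes / self.wells_per_plate)
        if self.n_plates is None:
            self.n_plates = needed
        elif self.n_plates < needed:
            raise ValueError(f"n_plates = {self.n_plates} cannot hold "
                             f"{self.n_genes} genes at {self.wells_per_plate}/plate")

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_counts(rng, lam, noise_free: bool, dispersion: float | None):
    lam = np.asarray(lam, dtype=float)
    if noise_free:
        return np.rint(lam).astype(np.int64)
    if dispersion:
        shape = 1.0 / dispersion
        return np.asarray(rng.poisson(rng.gamma(shape, lam * dispersion)), dtype=np.int64)
    return np.asarray(rng.poisson(lam), dtype=np.int64)


def simulate_screen(config: ScreenSimConfig):
    """Simulate a whole screen; returns (well records, true-effect table).

    Every gene gets one well on an unirradiated plate and one on the paired
    screening-dose plate, per run; irradiated expectations are
    cells_plated * base_pe * plate_effect * SF(dose; alpha0 * m_g, beta0).
    Replicate runs share the true-effect table but redraw plate effects and
    counts.  NT controls have multiplier 1; positive controls a strong
    fixed multiplier so controls separate (Z-factor > 0 at default noise).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"GENE{i:05d}" for i in range(cfg.n_genes)])
    n_hits = int(round(cfg.hit_fraction * cfg.n_genes))
    hit_idx = rng.choice(cfg.n_genes, size=n_hits, replace=False)
    mult = np.ones(cfg.n_genes)
    lo, hi = cfg.hit_effect_range
    mult[hit_idx] = rng.uniform(lo, hi, size=n_hits)
    is_hit = np.zeros(cfg.n_genes, dtype=bool)
    is_hit[hit_idx] = True

    truth = pd.DataFrame({
        "gene_id": np.append(genes, ["NT", "POS"]),
        "alpha_multiplier": np.append(mult, [1.0, cfg.pos_ctrl_multiplier]),
        "is_hit": np.append(is_hit, [False, False]),
        "is_nt_control": [False] * cfg.n_genes + [True, False],
        "is_pos_control": [False] * cfg.n_genes + [False, True],
    })

    sf_gene = np.exp(-(cfg.alpha0 * mult * cfg.dose + cfg.beta0 * cfg.dose**2))
    sf_nt = lq_survival(cfg.dose, cfg.alpha0, cfg.beta0)
    sf_pos = lq_survival(cfg.dose, cfg.alpha0 * cfg.pos_ctrl_multiplier, cfg.beta0)

    frames = []
    for run in range(1, cfg.n_replicate_runs + 1):
        run_id = f"run{run}"
        for plate in range(cfg.n_plates):
            start = plate * cfg.wells_per_plate
            gidx = np.arange(start, min(start + cfg.wells_per_plate, cfg.n_genes))
            targets = np.concatenate([
                genes[gidx],
                np.repeat("NT", cfg.nt_wells_per_plate),
                np.repeat("POS", cfg.pos_ctrl_wells_per_plate)])
            roles = np.concatenate([
                np.repeat("sample", len(gidx)),
                np.repeat("nt_control", cfg.nt_wells_per_plate),
                np.repeat("pos_control", cfg.pos_ctrl_wells_per_plate)])
            sf = np.concatenate([
                sf_gene[gidx],
                np.repeat(sf_nt, cfg.nt_wells_per_plate),
                np.repeat(sf_pos, cfg.pos_ctrl_wells_per_plate)])
            eff0 = math.exp(rng.normal(0.0, cfg.plate_effect_sd)) if cfg.plate_effect_sd else 1.0
            effd = math.exp(rng.normal(0.0, cfg.plate_effect_sd)) if cfg.plate_effect_sd else 1.0
            base = cfg.cells_plated * cfg.base_pe
            n = len(targets)
            wids = [_well_id(p) for p in range(n)]
            for arm_dose, eff in ((0.0, eff0), (cfg.dose, effd)):
                lam = base * eff * (np.ones(n) if arm_dose == 0 else sf)
                counts = _draw_counts(rng, lam, cfg.noise_free, cfg.dispersion)
                frames.append(pd.DataFrame({
                    "run_id": run_id,
                    # one physical plate per dose arm, paired by the base id
                    "plate_id": f"P{plate + 1:03d}-{arm_dose:g}Gy",
                    "well_id": wids,
                    "target": targets,
                    "sirna_id": np.char.add("si-", targets.astype(str)),
                    "dose": arm_dose,
                    "cells_plated": cfg.cells_plated,
                    "colonies": counts,
                    "role": roles,
                }))
    wells = pd.concat(frames, ignore_index=True)
    return wells, truth


def screen_layout(config: ScreenSimConfig, plate: int = 0) -> pd.DataFrame:
    """Plate layout table (well_id, target, sirna_id, role) for one plate."""
    cfg = config
    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    start = plate * cfg.wells_per_plate
    gidx = genes[start:start + cfg.wells_per_plate]
    targets = gidx + ["NT"] * cfg.nt_wells_per_plate + ["POS"] * cfg.pos_ctrl_wells_per_plate
    roles = (["sample"] * len(gidx) + ["nt_control"] * cfg.nt_wells_per_plate
             + ["pos_control"] * cfg.pos_ctrl_wells_per_plate)
    return pd.DataFrame({
        "well_id": [_well_id(p) for p in range(len(targets))],
        "target": targets,
        "sirna_id": [f"si-{t}" for t in targets],
        "role": roles,
    })


def simulate_survival_experiment(alpha: float, beta: float, doses, cells_plated: int,
                                 n_reps: int, seed: int, base_pe: float = 0.5,
                                 noise_free: bool = False,
                                 condition: str = "sample") -> pd.DataFrame:
    """Poisson colony counts for a dose-response experiment.

    Expectation per well is cells_plated * base_pe * SF(D; alpha, beta).
    ``doses`` must include 0 Gy (SF is undefined without the unirradiated
    reference).  Returns a well-record table.
    """
    doses = [float(d) for d in doses]
    if 0.0 not in doses:
        raise ValueError("doses must include 0 Gy (SF undefined without it)")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    if cells_plated < 1 or n_reps < 1:
        raise ValueError("cells_plated and n_reps must be >= 1")
    if not 0 < base_pe <= 1:
        raise ValueError("base_pe must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        for i, d in enumerate(doses):
            lam = cells_plated * base_pe * lq_survival(d, alpha, beta)
            count = int(_draw_counts(rng, lam, noise_free, None))
            rows.append({"run_id": "run1", "plate_id": f"P{rep:03d}",
                         "well_id": _well_id(i), "target": condition,
                         "sirna_id": f"si-{condition}", "dose": d,
                         "cells_plated": cells_plated, "colonies": count})
    return pd.DataFrame(rows)


def simulate_lineage_log(n_lineages: int, p_death_interphase: float,
                         p_death_mitosis: float, p_polyploid: float,
                         mitosis_length_mean: float = 45.0, seed: int = 0):
    """Two-generation branching lineage logs with known true fates.

    Per cell, mutually exclusive outcomes are drawn: death in interphase,
    death in mitosis (condensation followed by death), polyploidization
    (karyokinesis without cytokinesis for the founder; fusion of the two
    daughters after division), or normal progression.  Returns
    (event table, truth table) where the truth table carries the fate and
    polyploidization flag the generator actually produced — the classifier
    oracle for round-trip tests.
    """
    for name, p in [("p_death_interphase", p_death_interphase),
                    ("p_death_mitosis", p_death_mitosis),
                    ("p_polyploid", p_polyploid)]:
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if p_death_interphase + p_death_mitosis + p_polyploid > 1:
        raise ValueError("per-cell outcome probabilities must sum to <= 1")
    if mitosis_length_mean <= 0:
        raise ValueError("mitosis_length_mean must be > 0")
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    rng = np.random.default_rng(seed)
    p_di, p_dm, p_pp = p_death_interphase, p_death_mitosis, p_polyploid

    def outcome(allow_poly: bool) -> str:
        u = rng.random()
        if u < p_di:
            return "death_interphase"
        if u < p_di + p_dm:
            return "death_mitosis"
        if allow_poly and u < p_di + p_dm + p_pp:
            return "polyploid"
        return "normal"

    def mlen() -> float:
        return max(4.0, rng.normal(mitosis_length_mean, mitosis_length_mean / 6.0))

    events, truths = [], []
    for li in range(n_lineages):
        lid = f"L{li:05d}"
        deaths = []  # (time, phase)
        poly = False

        def add(cell, parent, event, t, phase=None):
            events.append({"lineage_id": lid, "cell_id": cell, "parent_id": parent,
                           "event": event, "time_min": round(float(t), 1),
                           "phase_at_death": phase})

        root = f"{lid}.1"
        inter = rng.uniform(600.0, 1200.0)
        root_out = outcome(allow_poly=True)
        if root_out == "death_interphase":
            t = rng.uniform(0.0, inter)
            add(root, None, "death", t, "interphase")
            deaths.append((t, "interphase"))
        elif root_out == "death_mitosis":
            add(root, None, "condensation_start", inter)
            t = inter + rng.uniform(0.0, mlen())
            add(root, None, "death", t, "mitosis")
            deaths.append((t, "mitosis"))
        elif root_out == "polyploid":
            ml = mlen()
            add(root, None, "condensation_start", inter)
            add(root, None, "karyokinesis_complete", inter + ml)
            poly = True
        else:
            ml = mlen()
            add(root, None, "condensation_start", inter)
            add(root, None, "karyokinesis_complete", inter + 0.9 * ml)
            t_div = inter + ml
            add(root, None, "cytokinesis_complete", t_div)
            d1, d2 = f"{lid}.2", f"{lid}.3"
            if rng.random() < p_pp:
                t_fuse = t_div + rng.uniform(30.0, 120.0)
                add(d1, root, "daughter_fusion", t_fuse)
                add(d2, root, "daughter_fusion", t_fuse)
                poly = True
            else:
                for daughter in (d1, d2):
                    inter2 = rng.uniform(600.0, 1200.0)
                    d_out = outcome(allow_poly=False)
                    if d_out == "death_interphase":
                        t = t_div + rng.uniform(0.0, inter2)
                        add(daughter, root, "death", t, "interphase")
                        deaths.append((t, "interphase"))
                    elif d_out == "death_mitosis":
                        t_c = t_div + inter2
                        add(daughter, root, "condensation_start", t_c)
                        t = t_c + rng.uniform(0.0, mlen())
                        add(daughter, root, "death", t, "mitosis")
                        deaths.append((t, "mitosis"))
                    # else: daughter survives quietly to the end of the movie
        if deaths:
            deaths.sort()
            fate = "death_interphase" if deaths[0][1] == "interphase" else "death_mitosis"
            poly_flag = False
        else:
            fate = "surviving"
            poly_flag = poly
        truths.append({"lineage_id": lid, "fate": fate, "polyploidization": poly_flag})
    ev = pd.DataFrame(events)
    ev = ev.sort_values(["lineage_id", "time_min", "cell_id"], ignore_index=True)
    return ev, pd.DataFrame(truths)


def lineage_fate_probabilities(p_death_interphase: float, p_death_mitosis: float,
                               p_polyploid: float) -> dict:
    """Closed-form fate probabilities implied by the lineage generator.

    Survival requires the founder to polyploidize, or to divide with the
    daughters fusing or both daughters surviving; the death/survival split is
    timing-independent, so it serves as an analytic oracle for recovery
    tests.  (The interphase/mitosis death split depends on event timing and
    is not reported here.)
    """
    d = p_death_interphase + p_death_mitosis
    q = p_polyploid
    w = 1.0 - d - q                      # founder divides
    p_surv = q + w * (q + (1 - q) * (1 - d) ** 2)
    return {"surviving": p_surv, "death": 1.0 - p_surv}


def simulate_metaphase_counts(mean_chromatid: float, mean_chromosome: float,
                              n_metaphases: int, mitotic_fraction: float,
                              seed: int = 0, condition: str = "treated",
                              timepoint: float = 0.0,
                              class_split=(0.6, 0.3, 0.1)):
    """Poisson per-metaphase aberration counts by class.

    The chromatid- and chromosome-type means are split over breaks, gaps and
    exchanges by ``class_split``.  Returns (MetaphaseRecord table,
    mitotic_fraction) so downstream per-100-cells estimation has both inputs.
    """
    if mean_chromatid < 0 or mean_chromosome < 0:
        raise ValueError("class means must be >= 0")
    if not 0 <= mitotic_fraction <= 1:
        raise ValueError("mitotic_fraction must lie in [0, 1]")
    if n_metaphases < 1:
        raise ValueError("n_metaphases must be >= 1")
    split = np.asarray(class_split, dtype=float)
    if split.shape != (3,) or (split < 0).any() or not math.isclose(split.sum(), 1.0):
        raise ValueError("class_split must be three non-negative fractions summing to 1")
    rng = np.random.default_rng(seed)
    data = {"condition": condition, "timepoint": timepoint}
    for prefix, mean in (("chromatid", mean_chromatid), ("chromosome", mean_chromosome)):
        for cls, frac in zip(("breaks", "gaps", "exchanges"), split):
            data[f"{prefix}_{cls}"] = rng.poisson(mean * frac, size=n_metaphases)
    return pd.DataFrame(data), float(mitotic_fraction)
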