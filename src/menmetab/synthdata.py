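"""Seeded synthetic meningioma-like metabolomic cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, at the dimensions of the motivating cohort: 43 samples by 270
metabolites, two metabolic clusters of 15 and 28 samples, the second
splitting into two subtypes (13 + 15).  On the log2 scale each metabolite
is

    baseline + subtype effect + module latent factor * loading + noise,

exponentiated to a positive raw intensity.  Three of the five planted
co-abundance modules are anchored on the subtype signature pathways
(glycine/serine for subtype I, choline for cluster II as a whole,
tryptophan/kynurenine for subtype II-b), so module eigengenes carry the
clinical contrasts the analysis is meant to recover.  Clinical covariates
are drawn with per-cluster margins matching the cohort's baseline table
in expectation (or exactly, with ``exact_margins=True``), and
progression-free survival is exponential per cluster with administrative
censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable, MetaboliteMatrix, LOCATIONS
from .spectra import Spectrum, TemplateLibrary

SUBTYPES = ("I", "II-a", "II-b")

DEFAULT_SIGNATURES: dict[str, tuple[str, ...]] = {
    "I": ("glycine", "serine", "arginine", "creatine", "glutamate"),
    "II-a": ("choline", "phosphocholine", "sphingosine", "isoleucine"),
    "II-b": ("tryptophan", "kynurenine", "kynurenic_acid", "choline"),
}

# per-cluster clinical margins mirrored from the cohort's baseline table
_SEX_MALE = (2 / 15, 8 / 28)
_AGE = ((62.3, 13.1), (64.4, 12.8))
_SIZE = ((48.3, 51.8), (88.6, 103.3))
_LOCATION_COUNTS = {
    1: {"falx": 3, "convexity": 2, "frontobasal": 4, "sphenoid wing": 2,
        "petroclival": 1, "spinal": 2, "others": 1},
    2: {"falx": 3, "convexity": 10, "frontobasal": 5, "sphenoid wing": 4,
        "petroclival": 1, "spinal": 1, "others": 4},
}
_SIMPSON_COUNTS = {1: {1: 5, 2: 9, 3: 0, 4: 1}, 2: {1: 7, 2: 16, 3: 3, 4: 2}}
_SEX_COUNTS = {1: {"male": 2, "female": 13}, 2: {"male": 8, "female": 20}}
_EDEMA_COUNTS = {1: {"high": 4, "low": 11}, 2: {"high": 18, "low": 10}}
_KPS_PRE = (78.0, 68.0)   # cluster medians near 80 vs 70
_KPS_POST = (88.0, 70.0)


class ConfigError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclass
class SimulationConfig:
    """All dials of the cohort generator, defaulting to the study conditions."""

    n_samples: int = 43
    n_metabolites: int = 270
    cluster_sizes: tuple[int, int, int] = (15, 13, 15)  # I, II-a, II-b
    signature_sets: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIGNATURES.items()})
    effect_size: float = 1.0          # log2 fold-change of signature metabolites
    n_modules: int = 5
    module_size: int = 12
    module_loading: float = 0.6       # rho, within-module latent-factor loading
    anchor_activation: float = 4.0    # factor-mean shift of anchored modules,
                                      # in units of effect_size
    noise_sd: float = 0.5             # residual SD, log2 scale
    mib1_means: tuple[float, float, float] = (1.2, 2.1, 11.7)
    edema_probs: tuple[float, float] = (4 / 15, 18 / 28)
    pfs_hazards: tuple[float, float] = (0.01, 0.05)  # events per month, per cluster
    censor_horizon: float = 60.0      # months
    exact_margins: bool = False
    seed: int = 0

    def validate(self) -> None:
        if sum(self.cluster_sizes) != self.n_samples:
            raise ConfigError(
                f"cluster_sizes {self.cluster_sizes} must sum to n_samples "
                f"{self.n_samples}")
        if not (0 <= self.module_loading < 1):
            raise ConfigError(f"module_loading must be in [0, 1), got "
                              f"{self.module_loading}")
        if self.noise_sd < 0 or any(h < 0 for h in self.pfs_hazards):
            raise ConfigError("rates and noise SD must be non-negative")
        if any(not (0 <= p <= 1) for p in self.edema_probs):
            raise ConfigError(f"edema_probs must be probabilities, got "
                              f"{self.edema_probs}")
        names = set(self.metabolite_names())
        for sub, sig in self.signature_sets.items():
            missing = set(sig) - names
            if missing:
                raise ConfigError(
                    f"signature metabolites of subtype {sub} not in metabolite "
                    f"list: {sorted(missing)}")
        if self.n_modules * self.module_size > self.n_metabolites:
            raise ConfigError("modules do not fit into the metabolite list")

    def metabolite_names(self) -> list[str]:
        """Named metabolites first (template library order), numbered fill after."""
        named = list(TemplateLibrary.builtin().metabolites)[: self.n_metabolites]
        fill = [f"metabolite_{i:03d}" for i in range(len(named) + 1,
                                                     self.n_metabolites + 1)]
        return named + fill


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort."""

    subtype_labels: pd.Series        # sample -> I / II-a / II-b
    cluster_labels: pd.Series        # sample -> 1 / 2
    module_assignment: pd.Series     # metabolite -> module id or 'none'
    signature_flags: dict[str, list[str]]  # metabolite -> subtypes it marks
    shift_offsets: dict[str, float] = field(default_factory=dict)

    @property
    def differential_metabolites(self) -> set[str]:
        """All metabolites with a planted between-group mean difference.

        Signature metabolites plus every member of the anchored modules
        (whose latent factors are mean-shifted between subtypes).
        """
        anchored = self.module_assignment.index[
            self.module_assignment.isin(["mod1", "mod2", "mod3"])]
        return set(anchored) | set(self.signature_flags)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype_labels": self.subtype_labels.to_dict(),
            "cluster_labels": {k: int(v) for k, v in
                               self.cluster_labels.to_dict().items()},
            "module_assignment": self.module_assignment.to_dict(),
            "signature_flags": self.signature_flags,
            "shift_offsets": self.shift_offsets,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            subtype_labels=pd.Series(raw["subtype_labels"]),
            cluster_labels=pd.Series(raw["cluster_labels"]),
            module_assignment=pd.Series(raw["module_assignment"]),
            signature_flags=raw["signature_flags"],
            shift_offsets=raw.get("shift_offsets", {}),
        )


def _plant_modules(cfg: SimulationConfig, names: list[str]) -> dict[str, list[str]]:
    """Assign metabolites to modules; first three anchored on signature sets.

    Fill members come from the unnamed (numbered) metabolites so that the
    named pathway library stays orthogonal to module filler — only the
    planted pathways should appear differential or enriched.
    """
    assigned: set[str] = set()
    modules: dict[str, list[str]] = {}
    anchors = [list(cfg.signature_sets.get(s, [])) for s in SUBTYPES]
    sig_names = {m for a in anchors for m in a}
    numbered = [n for n in names if n.startswith("metabolite_")]
    other = [n for n in names if not n.startswith("metabolite_")
             and n not in sig_names]
    pool_iter = iter(numbered + other)
    for m in range(cfg.n_modules):
        label = f"mod{m + 1}"
        members: list[str] = []
        if m < len(anchors):
            members = [x for x in anchors[m] if x not in assigned]
        while len(members) < cfg.module_size:
            members.append(next(pool_iter))
        modules[label] = members
        assigned.update(members)
    return modules


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[MetaboliteMatrix, ClinicalTable, CohortTruth]:
    """Draw one full synthetic cohort (intensity matrix, clinical table, truth).

    Identical config (including seed) gives bit-identical outputs.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = cfg.metabolite_names()
    n = cfg.n_samples
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]

    sizes = cfg.cluster_sizes
    subtype = np.repeat(SUBTYPES, sizes)
    cluster = np.where(subtype == "I", 1, 2)

    # --- intensity matrix -------------------------------------------------
    baseline = rng.normal(0.0, 1.0, size=len(names))
    log2x = np.tile(baseline, (n, 1))

    sig_flags: dict[str, list[str]] = {}
    for sub in SUBTYPES:
        for met in cfg.signature_sets.get(sub, []):
            sig_flags.setdefault(met, []).append(sub)
            j = names.index(met)
            log2x[subtype == sub, j] += cfg.effect_size

    modules = _plant_modules(cfg, names)
    # anchored-module factors carry the planted clinical contrasts: mod1 is
    # elevated in subtype I, mod2 (choline) in the whole second cluster,
    # mod3 (tryptophan) in subtype II-b; mod4+ are pure co-abundance
    factor_shift = {
        "mod1": (subtype == "I").astype(float),
        "mod2": (cluster == 2).astype(float),
        "mod3": (subtype == "II-b").astype(float),
    }
    for label, members in modules.items():
        f = rng.normal(0.0, 1.0, size=n)
        f = f + cfg.anchor_activation * cfg.effect_size * factor_shift.get(label, 0.0)
        cols = [names.index(m) for m in members]
        log2x[:, cols] += cfg.module_loading * f[:, None]

    log2x += rng.normal(0.0, cfg.noise_sd, size=log2x.shape)
    values = pd.DataFrame(2.0**log2x, index=sample_ids, columns=names)
    matrix = MetaboliteMatrix(values=values, state="raw")

    # --- clinical table ---------------------------------------------------
    clin = _simulate_clinical(cfg, rng, sample_ids, subtype, cluster)

    module_assignment = pd.Series("none", index=names, name="module")
    for label, members in modules.items():
        module_assignment[members] = label
    truth = CohortTruth(
        subtype_labels=pd.Series(subtype, index=sample_ids, name="subtype"),
        cluster_labels=pd.Series(cluster, index=sample_ids, name="cluster"),
        module_assignment=module_assignment,
        signature_flags=sig_flags,
    )
    return matrix, clin, truth


def _fill_counts(counts: Mapping, size: int, rng) -> np.ndarray:
    """Deterministic level vector from exact counts (order fixed)."""
    out = []
    for level, c in counts.items():
        out.extend([level] * c)
    assert len(out) == size, (counts, size)
    return np.array(out, dtype=object)


def _draw_counts(counts: Mapping, size: int, rng) -> np.ndarray:
    levels = list(counts)
    probs = np.array([counts[l] for l in levels], dtype=float)
    probs /= probs.sum()
    return rng.choice(np.array(levels, dtype=object), size=size, p=probs)


def _simulate_clinical(cfg, rng, sample_ids, subtype, cluster) -> ClinicalTable:
    n = len(sample_ids)
    d = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    d["cluster"] = cluster
    d["subtype"] = subtype
    c1 = cluster == 1
    pick = _fill_counts if cfg.exact_margins else _draw_counts

    for col, table in (("sex", _SEX_COUNTS), ("location", _LOCATION_COUNTS),
                       ("simpson", _SIMPSON_COUNTS)):
        vals = np.empty(n, dtype=object)
        vals[c1] = pick(table[1], int(c1.sum()), rng)
        vals[~c1] = pick(table[2], int((~c1).sum()), rng)
        d[col] = vals
    # edema uses the configured per-cluster Bernoulli rates
    if cfg.exact_margins:
        vals = np.empty(n, dtype=object)
        vals[c1] = _fill_counts(_EDEMA_COUNTS[1], int(c1.sum()), rng)
        vals[~c1] = _fill_counts(_EDEMA_COUNTS[2], int((~c1).sum()), rng)
        d["edema"] = vals
    else:
        p = np.where(c1, cfg.edema_probs[0], cfg.edema_probs[1])
        d["edema"] = np.where(rng.random(n) < p, "high", "low")

    for col, (m1, m2) in (("age", _AGE), ):
        vals = np.where(c1, rng.normal(m1[0], m1[1], n), rng.normal(m2[0], m2[1], n))
        d[col] = np.clip(vals, 18.0, 95.0)
    # tumor volume: lognormal matched to per-cluster mean and SD
    size_vals = np.empty(n)
    for grp, (mean, sd) in zip((c1, ~c1), _SIZE):
        sigma2 = np.log(1 + (sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        size_vals[grp] = rng.lognormal(mu, np.sqrt(sigma2), int(grp.sum()))
    d["size_cm3"] = size_vals

    for col, med in (("kps_pre", _KPS_PRE), ("kps_post", _KPS_POST)):
        raw = np.where(c1, rng.normal(med[0], 10.0, n), rng.normal(med[1], 12.0, n))
        d[col] = np.clip(np.round(raw / 10) * 10, 40, 100)

    # MIB-1: per-subtype lognormal with mean exactly the configured center
    sigma = 0.25
    mib = np.empty(n)
    for sub, m in zip(SUBTYPES, cfg.mib1_means):
        sel = subtype == sub
        mu = np.log(m) - sigma**2 / 2
        mib[sel] = rng.lognormal(mu, sigma, int(sel.sum()))
    if cfg.exact_margins:
        # reproduce the proliferation margins (15/0 vs 9/19 below/above 5%)
        mib = np.where(c1, 1.2, np.nan)
        idx2 = np.flatnonzero(~c1)
        mib[idx2[:9]] = 2.1
        mib[idx2[9:]] = 11.7
    d["mib1"] = mib

    # WHO grade: subtype I and II-a benign; II-b carries grades II and III
    grade = np.where(subtype == "II-b", "II", "I").astype(object)
    iib = np.flatnonzero(subtype == "II-b")
    grade[iib[-3:]] = "III"
    d["who_grade"] = grade

    hazard = np.where(c1, cfg.pfs_hazards[0], cfg.pfs_hazards[1])
    draw = rng.exponential(1.0 / np.where(hazard > 0, hazard, np.inf), n)
    d["pfs_time"] = np.minimum(draw, cfg.censor_horizon)
    d["pfs_event"] = (draw < cfg.censor_horizon).astype(int)
    return ClinicalTable(d)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSet:
    spectra: list[Spectrum]
    shifts: dict[str, float]  # sample id -> applied ppm offset

    def write_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sp in self.spectra:
            sp.to_csv(directory / f"{sp.sample_id}.csv")


def simulate_spectra(
    matrix: MetaboliteMatrix,
    config: SimulationConfig | None = None,
    library: TemplateLibrary | None = None,
    max_shift: float = 0.02,
) -> SpectrumSet:
    """Render each sample's intensities to a toy 1D spectrum.

    Peak areas are proportional to the sample's metabolite intensities; a
    lactate doublet near 1.310 ppm is always present and is boosted to
    dominate the other peaks in its neighborhood (as lactate does in real
    tumor extracts — the reason it serves as the alignment reference).
    Each sample gets a random chemical-shift offset within +/- max_shift
    ppm, applied to every peak center and recorded in the returned set.
    """
    from .spectra import default_grid

    cfg = config or SimulationConfig()
    lib = library or TemplateLibrary.builtin()
    missing = [m for m in matrix.metabolite_names if m not in lib.peaks]
    if missing:
        raise KeyError(f"no spectral templates for metabolites: {missing[:10]}"
                       f"{' ...' if len(missing) > 10 else ''}")
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the cohort stream
    ppm = default_grid()
    spectra, shifts = [], {}
    for sid in matrix.sample_ids:
        delta = float(rng.uniform(-max_shift, max_shift))
        inten = np.zeros_like(ppm)
        sample = matrix.values.loc[sid]
        for met, amount in sample.items():
            if met == "l_lactic_acid":
                continue
            inten += amount * _shifted_template(lib, met, ppm, delta)
        # dominant lactate reference: at least 2x the largest other signal
        lactate = float(sample.get("l_lactic_acid", 0.0))
        lactate = max(lactate, 2.0 * float(sample.drop(
            "l_lactic_acid", errors="ignore").max()))
        inten += lactate * _shifted_template(lib, "l_lactic_acid", ppm, delta)
        spectra.append(Spectrum(ppm=ppm.copy(), intensity=inten, sample_id=sid))
        shifts[sid] = delta
    return SpectrumSet(spectra=spectra, shifts=shifts)


def _shifted_template(lib: TemplateLibrary, name: str, ppm: np.ndarray,
                      delta: float) -> np.ndarray:
    out = np.zeros_like(ppm)
    for center, area, hwhm in lib.peaks[name]:
        out += area * (hwhm / np.pi) / ((ppm - (center + delta)) ** 2 + hwhm**2)
    return out
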