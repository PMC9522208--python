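"""Synthetic specimen tables and trees with the structure the analysis
assumes: power-law spiracle dimensions in body mass with lognormal
noise, optional phylogenetically correlated deviations, and the study
design of 17 specimens from 10 species (1-2 each) spanning 0.097-18 g.

The generator matches structure, not any real specimen's values.  Its
defaults encode the study conditions: isometric true exponents (area
0.67, depth 0.33), a mesothoracic spiracle ~4x the area of the
metathoracic and first abdominal spiracles with the last three
abdominal ones ~half the size of the anterior abdominals, slit-like
openings (transverse/sagittal diameter ratio 2), tighter area scatter
anteriorly than posteriorly, and absolute intercepts placing a 1 g
beetle's doubled summed area/depth near 0.25 cm so the resulting
resting dPO2 spans roughly 0.05-0.5 kPa over the mass range.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .morphometry import (
    SPIRACLE_LABELS,
    Specimen,
    SpiracleMeasurement,
    write_measurement_table,
)
from .phylo import PhyloTree, parse_newick

#: Relative area weights, anterior to posterior (S 4x T/A1-A3, A4-A6 half).
_AREA_WEIGHTS = (4.0, 1.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5)
#: Unit-weight opening area of a 1 g beetle, cm^2 (see module docstring).
_BASE_AREA_1G = 6.58e-4
#: Spiracle depth of a 1 g beetle, cm.
_BASE_DEPTH_1G = 0.05

DEFAULT_AREA_INTERCEPTS = tuple(
    math.log10(w * _BASE_AREA_1G) for w in _AREA_WEIGHTS
)
DEFAULT_DEPTH_INTERCEPTS = (math.log10(_BASE_DEPTH_1G),) * 8
#: log10 scatter of area, loosening toward the posterior spiracles.
DEFAULT_AREA_NOISE = (0.05, 0.08, 0.10, 0.10, 0.12, 0.20, 0.22, 0.25)
#: log10 scatter of depth, similar at every position.
DEFAULT_DEPTH_NOISE = (0.08,) * 8


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    Masses are drawn log-uniformly over ``mass_range`` (g); for each
    spiracle, log10 dimension = intercept + exponent * log10 mass
    + phylo deviation + N(0, noise sd).  ``lambda_signal`` scales a
    Brownian-motion deviation simulated on the tree (0 = none).
    """

    n_species: int = 10
    specimens_per_species: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 2, 1, 1, 1)
    mass_range: tuple[float, float] = (0.097, 18.0)
    area_exponent: float = 0.67
    depth_exponent: float = 0.33
    area_intercepts: tuple[float, ...] = DEFAULT_AREA_INTERCEPTS
    depth_intercepts: tuple[float, ...] = DEFAULT_DEPTH_INTERCEPTS
    area_noise_sd: tuple[float, ...] = DEFAULT_AREA_NOISE
    depth_noise_sd: tuple[float, ...] = DEFAULT_DEPTH_NOISE
    lambda_signal: float = 0.0
    phylo_sd: float = 0.1
    eccentricity: float = 2.0     # d_transverse / d_sagittal, slit-like
    within_species_mass_jitter: float = 0.05  # log10 sd between conspecifics
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.mass_range
        if not (0 < lo < hi):
            raise ValueError("mass_range must be positive and ordered")
        if len(self.specimens_per_species) != self.n_species:
            raise ValueError("specimens_per_species must have n_species entries")
        for name in ("area_intercepts", "depth_intercepts", "area_noise_sd",
                     "depth_noise_sd"):
            if len(getattr(self, name)) != 8:
                raise ValueError(f"{name} must have 8 entries")
        if any(s < 0 for s in self.area_noise_sd + self.depth_noise_sd):
            raise ValueError("noise sd must be >= 0")
        if not (0.0 <= self.lambda_signal <= 1.0):
            raise ValueError("lambda_signal must be in [0, 1]")

    @property
    def n_specimens(self) -> int:
        return sum(self.specimens_per_species)

    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


def generate_tree(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Random rooted species tree: uniform coalescent-style pairwise
    joins, unit branch lengths."""
    if cfg.n_species < 2:
        raise ValueError("need at least 2 species for a tree")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lineages = [f"{name}:1" for name in cfg.species_names()]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        merged = f"({lineages[i]},{lineages[j]}):1"
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)]
        lineages.append(merged)
    newick = lineages[0].rsplit(":", 1)[0] + ";"
    return parse_newick(newick)


def _phylo_deviations(
    tree: PhyloTree, species: list[str], lam: float, sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Brownian deviation per species, covariance lam * sd^2 * C
    where C is the shared-branch matrix (diagonal kept at tip depth)."""
    if lam == 0.0 or sd == 0.0:
        return np.zeros(len(species))
    depths = tree.tip_depths()
    n = len(species)
    C = np.empty((n, n))
    for i, a in enumerate(species):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = tree.shared_depth(a, species[j])
    scale = np.mean(np.diag(C))
    cov = lam * sd**2 * C / scale  # normalise so tip variance ~ lam*sd^2
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return L @ rng.standard_normal(n)


def _diameters_for_area(area_cm2: float, ecc: float) -> tuple[float, float]:
    """Diameter pair (mm) with ratio ecc whose ellipse has the target area."""
    area_mm2 = area_cm2 * 100.0
    d_sag = math.sqrt(4.0 * area_mm2 / (math.pi * ecc))
    return ecc * d_sag, d_sag


def generate_specimens(
    cfg: GeneratorConfig,
    tree: PhyloTree | None = None,
    rng: np.random.Generator | None = None,
) -> list[Specimen]:
    """Draw a full synthetic specimen table under ``cfg``.

    With all noise and ``lambda_signal`` zero, every log-log regression
    recovers the configured exponents exactly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if tree is None and cfg.lambda_signal > 0:
        tree = generate_tree(cfg, rng=rng)

    species = cfg.species_names()
    lo, hi = cfg.mass_range
    log_mass_sp = rng.uniform(math.log10(lo), math.log10(hi), size=cfg.n_species)

    # one species-level Brownian deviation per trait family
    if tree is not None:
        dev_area = _phylo_deviations(tree, species, cfg.lambda_signal, cfg.phylo_sd, rng)
        dev_depth = _phylo_deviations(tree, species, cfg.lambda_signal, cfg.phylo_sd, rng)
    else:
        dev_area = dev_depth = np.zeros(cfg.n_species)

    specimens = []
    for si, (name, k) in enumerate(zip(species, cfg.specimens_per_species)):
        for rep in range(k):
            lm = log_mass_sp[si]
            if k > 1:
                lm = lm + cfg.within_species_mass_jitter * rng.standard_normal()
            lm = min(max(lm, math.log10(lo)), math.log10(hi))
            mass = 10.0**lm
            spiracles = []
            for pos, label in enumerate(SPIRACLE_LABELS):
                log_area = (
                    cfg.area_intercepts[pos]
                    + cfg.area_exponent * lm
                    + dev_area[si]
                    + cfg.area_noise_sd[pos] * rng.standard_normal()
                )
                log_depth = (
                    cfg.depth_intercepts[pos]
                    + cfg.depth_exponent * lm
                    + dev_depth[si]
                    + cfg.depth_noise_sd[pos] * rng.standard_normal()
                )
                d_t, d_s = _diameters_for_area(10.0**log_area, cfg.eccentricity)
                spiracles.append(
                    SpiracleMeasurement(
                        spiracle_label=label,
                        d_transverse=d_t,
                        d_sagittal=d_s,
                        depth=10.0**log_depth * 10.0,  # cm -> mm
                    )
                )
            specimens.append(
                Specimen(
                    specimen_id=f"{name}_{rep + 1}",
                    species=name,
                    sex=str(rng.choice(["M", "F"])),
                    mass=mass,
                    spiracles=tuple(spiracles),
                )
            )
    return specimens


def generate_study(
    cfg: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[list[Specimen], PhyloTree]:
    """Generate a full study (specimen table + tree) from one seed; if
    ``out_dir`` is given, write the measurement CSV, newick file and a
    JSON manifest recording the config for exact regeneration."""
    rng = np.random.default_rng(cfg.seed)
    tree = generate_tree(cfg, rng=rng)
    specimens = generate_specimens(cfg, tree=tree, rng=rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_measurement_table(specimens, out / "measurements.csv")
        (out / "tree.nwk").write_text(tree.as_newick() + "\n")
        (out / "manifest.json").write_text(
            json.dumps({"generator": asdict(cfg)}, indent=2) + "\n"
        )
    return specimens, tree
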