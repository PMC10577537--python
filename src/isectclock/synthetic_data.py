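"""Synthetic bisulfite-sequencing cohorts with age-linear CpG methylation.

Real training data for the clock are RRBS blood cohorts: per-CpG read counts
where a subset of sites drifts linearly with age. This module emulates that
structure so the whole workflow is testable without downloads:

* each CpG site has a baseline methylation percent; informative sites add a
  signed per-year slope times the sample's age, plus Gaussian biological
  noise, clipped to [0, 100];
* read depth is drawn from a negative-binomial-like distribution (default
  mean 30 with moderate overdispersion, capped at 200) so the >= 5-read
  coverage filter occasionally bites;
* methylated counts are a binomial draw of the depth at the latent percent;
* test samples cover only a random fraction of the sites (site-wise
  independent by default, or contiguous blocks emulating RRBS fragments).

Everything is reproducible from (spec, seed); the same spec seed fixes the
per-site baselines and slopes, so training cohorts and test samples generated
from one spec share a latent site model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .methylation_io import (
    FeatureTable,
    MethylationCallSet,
    build_feature_table,
)


class SpecError(ValueError):
    """Infeasible generator specification."""


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic methylation cohort.

    Defaults mirror the training conditions the clock targets: 182 samples,
    ages uniform on 4-40 years, 20,000 CpG sites of which 300 carry an
    age-linear signal with slopes of 0.1-0.5 percent/year (random sign),
    biological noise of 2 percentage points, and read depth around 30x.
    """

    n_samples: int = 182
    n_sites: int = 20_000
    n_informative: int = 300
    age_range: tuple[float, float] = (4.0, 40.0)
    slope_magnitude: tuple[float, float] = (0.1, 0.5)  # percent per year
    baseline_range: tuple[float, float] = (20.0, 80.0)
    noise_sd: float = 2.0  # percent points
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0  # negative-binomial size; larger = closer to Poisson
    depth_max: int = 200
    missing_fraction: float = 0.0
    block_missingness: bool = False
    chrom: str = "chr1"
    start_pos: int = 1_000
    spacing: int = 10
    assembly: str = "synthetic"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_sites:
            raise SpecError("n_informative cannot exceed n_sites")
        if self.n_samples < 1 or self.n_sites < 1:
            raise SpecError("n_samples and n_sites must be positive")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise SpecError("missing_fraction must be in [0, 1]")
        if self.age_range[0] < 0 or self.age_range[1] < self.age_range[0]:
            raise SpecError("age_range must be non-negative and ordered")
        if self.spacing < 2:
            raise SpecError("spacing must be >= 2 (CpG dinucleotides cannot overlap)")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0 or self.depth_max < 1:
            raise SpecError("depth parameters must be positive")


class _SiteModel:
    """Latent per-site parameters, fixed by the spec seed."""

    def __init__(self, spec: GeneratorSpec):
        rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 11]))
        self.positions = spec.start_pos + spec.spacing * np.arange(spec.n_sites)
        self.baselines = rng.uniform(*spec.baseline_range, spec.n_sites)
        self.slopes = np.zeros(spec.n_sites)
        self.informative_idx = rng.choice(spec.n_sites, spec.n_informative, replace=False)
        magnitudes = rng.uniform(*spec.slope_magnitude, spec.n_informative)
        signs = rng.choice([-1.0, 1.0], spec.n_informative)
        self.slopes[self.informative_idx] = magnitudes * signs

    def latent_percent(self, age: float, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
        latent = self.baselines + self.slopes * age
        if noise_sd > 0:
            latent = latent + rng.normal(0.0, noise_sd, latent.shape)
        return np.clip(latent, 0.0, 100.0)


def _draw_depth(
    spec: GeneratorSpec, n: int, rng: np.random.Generator, min_depth: int
) -> np.ndarray:
    if np.isinf(spec.depth_dispersion):  # zero-overdispersion limit: constant depth
        depth = np.full(n, int(round(spec.depth_mean)), dtype=np.int64)
    else:
        r = spec.depth_dispersion
        p = r / (r + spec.depth_mean)
        depth = rng.negative_binomial(r, p, n)
    return np.clip(depth, min_depth, spec.depth_max)


def _counts_from_latent(
    latent_percent: np.ndarray, depth: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    meth = rng.binomial(depth, latent_percent / 100.0)
    return meth, depth - meth


def _callset(spec: GeneratorSpec, sample_id: str, positions, meth, unmeth) -> MethylationCallSet:
    return MethylationCallSet.from_arrays(
        sample_id=sample_id,
        chrom=np.full(len(positions), spec.chrom, dtype=object),
        pos=positions,
        meth=meth,
        unmeth=unmeth,
        assembly=spec.assembly,
    )


def generate_training_cohort(
    spec: GeneratorSpec,
) -> tuple[list[MethylationCallSet], pd.DataFrame]:
    """Generate the training cohort: full site coverage, depth forced >= 5.

    Ages are uniform on ``spec.age_range``. Every site has at least 5 reads in
    every sample, so the assembled feature table keeps all ``n_sites`` columns.
    Returns the call sets plus a metadata table (sample_id, age, group).
    """
    model = _SiteModel(spec)
    root = np.random.SeedSequence([spec.rng_seed, 22])
    age_rng = np.random.default_rng(root.spawn(1)[0])
    ages = age_rng.uniform(*spec.age_range, spec.n_samples)
    callsets = []
    sample_streams = np.random.SeedSequence([spec.rng_seed, 33]).spawn(spec.n_samples)
    for i in range(spec.n_samples):
        rng = np.random.default_rng(sample_streams[i])
        latent = model.latent_percent(ages[i], spec.noise_sd, rng)
        depth = _draw_depth(spec, spec.n_sites, rng, min_depth=5)
        meth, unmeth = _counts_from_latent(latent, depth, rng)
        callsets.append(_callset(spec, f"train_{i:03d}", model.positions, meth, unmeth))
    metadata = pd.DataFrame(
        {"sample_id": [cs.sample_id for cs in callsets], "age": ages, "group": "training"}
    )
    return callsets, metadata


def training_feature_table(spec: GeneratorSpec) -> FeatureTable:
    """Convenience: generate the cohort and assemble its feature table."""
    callsets, metadata = generate_training_cohort(spec)
    return build_feature_table(callsets, metadata, assembly=spec.assembly)


def generate_test_sample(
    spec: GeneratorSpec,
    age: float,
    covered_fraction: float = 1.0,
    sample_id: str = "test",
    seed: Optional[int] = None,
    min_depth: int = 0,
) -> MethylationCallSet:
    """One test sample from the same latent site model, with partial coverage.

    A seeded random subset of ``covered_fraction`` of the sites receives reads
    (contiguous blocks when ``spec.block_missingness``); depths are drawn from
    the spec's depth model without the training floor, so some covered sites
    may still fail a downstream >= 5-read filter. ``age`` may lie outside the
    training range (extrapolation is legitimate use).
    """
    if not 0.0 <= covered_fraction <= 1.0:
        raise SpecError("covered_fraction must be in [0, 1]")
    model = _SiteModel(spec)
    if seed is None:
        ss = np.random.SeedSequence([spec.rng_seed, 44, zlib.crc32(sample_id.encode())])
    else:
        ss = np.random.SeedSequence([int(seed), 44])
    rng = np.random.default_rng(ss)
    n_cov = int(round(covered_fraction * spec.n_sites))
    if spec.block_missingness and n_cov < spec.n_sites:
        start = int(rng.integers(0, spec.n_sites - n_cov + 1))
        covered = np.arange(start, start + n_cov)
    else:
        covered = np.sort(rng.choice(spec.n_sites, n_cov, replace=False))
    latent = model.latent_percent(age, spec.noise_sd, rng)[covered]
    depth = _draw_depth(spec, n_cov, rng, min_depth=min_depth)
    meth, unmeth = _counts_from_latent(latent, depth, rng)
    return _callset(spec, sample_id, model.positions[covered], meth, unmeth)


def generate_rejuvenation_cohort(
    spec: GeneratorSpec,
    age_a: float,
    age_b: float,
    n_per_group: int,
    seed: Optional[int] = None,
    min_depth: int = 0,
) -> tuple[list[MethylationCallSet], dict[str, str]]:
    """Two test groups whose latent epigenetic ages are ``age_a`` and ``age_b``.

    Emulates a developmental-stage contrast (e.g. pre- vs post-rejuvenation):
    downstream group comparison should detect the designed difference. Returns
    the call sets and a sample_id -> group-label mapping ("A"/"B").
    """
    if n_per_group < 2:
        raise SpecError("n_per_group must be >= 2 for a group comparison")
    base = int(seed) if seed is not None else spec.rng_seed
    streams = np.random.SeedSequence([base, 55]).generate_state(2 * n_per_group) % 2**31
    callsets: list[MethylationCallSet] = []
    labels: dict[str, str] = {}
    covered = 1.0 - spec.missing_fraction
    for g, age in (("A", age_a), ("B", age_b)):
        for i in range(n_per_group):
            sid = f"{g}_{i:02d}"
            k = i if g == "A" else n_per_group + i
            callsets.append(
                generate_test_sample(
                    spec, age, covered_fraction=covered, sample_id=sid,
                    seed=int(streams[k]), min_depth=min_depth,
                )
            )
            labels[sid] = g
    return callsets, labels


# ---------------------------------------------------------------------------
# File output (CpG-report format, so fixtures feed the same readers as data)
# ---------------------------------------------------------------------------

def write_cpg_report(callset: MethylationCallSet, path) -> None:
    """Write as a Bismark-style CpG report with counts split across strands.

    Each collapsed site becomes a plus-strand row at its position and a
    minus-strand row one base downstream; the split is deterministic (plus
    strand takes the larger half), so reading the file back and re-collapsing
    reproduces the call set exactly.
    """
    chrom = callset.data.index.get_level_values("chrom")
    pos = callset.data.index.get_level_values("pos").to_numpy()
    meth = callset.data["meth"].to_numpy()
    unmeth = callset.data["unmeth"].to_numpy()
    mp, mm = (meth + 1) // 2, meth // 2
    up, um = (unmeth + 1) // 2, unmeth // 2
    plus = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "strand": "+", "meth": mp, "unmeth": up,
         "context": "CpG", "tri": "CGN"}
    )
    minus = pd.DataFrame(
        {"chrom": chrom, "pos": pos + 1, "strand": "-", "meth": mm, "unmeth": um,
         "context": "CpG", "tri": "CGN"}
    )
    out = pd.concat([plus, minus]).sort_values(["chrom", "pos"], kind="stable")
    out.to_csv(path, sep="\t", index=False, header=False)


def write_cohort(
    callsets: Sequence[MethylationCallSet], metadata: pd.DataFrame, out_dir
) -> None:
    """Write one CpG report per sample plus a metadata TSV into ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for cs in callsets:
        write_cpg_report(cs, os.path.join(out_dir, f"{cs.sample_id}.CpG_report.txt"))
    metadata.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t", index=False)
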