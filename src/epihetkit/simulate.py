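"""Synthetic bisulfite-epiallele data with known ground truth.

Three generators, all pure functions of their seed:

* :func:`simulate_profiles` — per-sample epiallele count tables for a
  two-group cohort under a hierarchical Dirichlet–multinomial model, with a
  configurable fraction of planted differential-heterogeneity (DEH) loci
  whose group-level compositions are calibrated so the expected metric
  difference equals a requested shift.
* :func:`simulate_module_cohort` — a node x sample heterogeneity matrix
  with planted correlated modules (latent-factor model) and a clinical
  trait driven by one module's factor.
* :func:`simulate_sam` — a SAM file (plus reference FASTA) whose reads'
  methylation-call strings realize a profile table's pattern counts
  exactly, for extraction round-trip testing.

Count model.  Each locus has a population epiallele composition pi over the
16 patterns: background loci draw pi once from a symmetric Dirichlet(alpha)
shared by both groups (alpha is the diversity knob: small alpha gives
clonal loci, large alpha near-uniform ones); planted DEH loci use
deterministic group-specific compositions that hit the requested metric
level exactly.  Each sample then draws replicate proportions from
Dirichlet(kappa * pi) — kappa sets biological/technical replicate noise —
and counts from a multinomial at a coverage drawn from a Poisson truncated
at the extraction coverage floor (emulating post-filter tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .epiallele import (
    N_PATTERNS,
    EpihetError,
    EpialleleProfile,
    LocusKey,
)

logger = logging.getLogger(__name__)

EPIPOLY_MAX = 1.0 - 1.0 / N_PATTERNS  # 0.9375


def alpha_for_epipolymorphism(mean_epipoly: float) -> float:
    """Symmetric-Dirichlet concentration with a given expected epipolymorphism.

    For pi ~ Dirichlet(alpha * 1_16), E[1 - sum(pi**2)] = 15*alpha/(16*alpha + 1),
    which inverts to alpha = m / (15 - 16*m) for m in (0, 0.9375).
    """
    if not (0 < mean_epipoly < EPIPOLY_MAX):
        raise EpihetError(
            f"expected epipolymorphism must lie in (0, {EPIPOLY_MAX}); got {mean_epipoly}"
        )
    return mean_epipoly / (15.0 - 16.0 * mean_epipoly)


def _blend(t: float, base: int) -> np.ndarray:
    """Composition (1-t)*e_base + (t/16)*uniform on the 16-simplex."""
    pi = np.full(N_PATTERNS, t / N_PATTERNS)
    pi[base] += 1.0 - t
    return pi


def _metric_of_blend(t: float, metric: str) -> float:
    # base pattern is concordant (code 0 or 15); all three metrics are then
    # symmetric in the choice of base.
    p_base = 1.0 - t + t / N_PATTERNS
    p_rest = t / N_PATTERNS
    if metric == "epipolymorphism":
        return 1.0 - (p_base ** 2 + 15.0 * p_rest ** 2)
    if metric == "pdr":
        # discordant mass: everything except the base concordant pattern and
        # the opposite concordant pattern
        return 1.0 - p_base - p_rest
    if metric == "shannon":
        h = 0.0
        for p in (p_base,) + (p_rest,) * 15:
            if p > 0:
                h -= p * np.log2(p)
        return h
    raise EpihetError(f"no calibration available for metric {metric!r}")


def composition_for_metric(level: float, metric: str, base: int = 0) -> np.ndarray:
    """Deterministic composition whose metric value equals ``level`` exactly.

    Blends a concordant one-hot pattern with the uniform distribution; the
    feasible range is [0, metric_of_uniform) and an out-of-range request is
    an error stating that range.
    """
    if base not in (0, N_PATTERNS - 1):
        raise EpihetError("base pattern must be a concordant code (0 or 15)")
    lo, hi = _metric_of_blend(0.0, metric), _metric_of_blend(1.0, metric)
    if not (lo <= level <= hi):
        raise EpihetError(
            f"requested {metric} level {level} outside the feasible range [{lo}, {hi:.4f}]"
        )
    if level == lo:
        return _blend(0.0, base)
    t = brentq(lambda t: _metric_of_blend(t, metric) - level, 0.0, 1.0)
    return _blend(t, base)


@dataclass
class SimulationSpec:
    """Study conditions for the two-group profile simulation."""

    seed: int
    n_loci: int = 1000
    n_samples: Tuple[int, int] = (8, 8)
    group_names: Tuple[str, str] = ("normal", "cancer")
    metric: str = "epipolymorphism"
    baseline_level: float = 0.2
    deh_fraction: float = 0.05
    shift: float = 0.4
    background_alpha: Optional[float] = None  # derived from baseline_level if None
    replicate_concentration: float = 300.0
    mean_coverage: float = 80.0
    min_coverage: int = 60
    chrom: str = "chr1"
    locus_spacing: int = 1000
    cpg_step: int = 10

    def __post_init__(self):
        if self.seed is None:
            raise EpihetError("a seed is mandatory")
        if self.n_loci < 1 or min(self.n_samples) < 1:
            raise EpihetError("n_loci and group sizes must be positive")
        if not (0 <= self.deh_fraction <= 1):
            raise EpihetError("deh_fraction must lie in [0, 1]")

    def resolved_alpha(self) -> float:
        if self.background_alpha is not None:
            return self.background_alpha
        return alpha_for_epipolymorphism(self.baseline_level)


@dataclass
class SimulatedCohort:
    profiles: Dict[str, List[EpialleleProfile]]  # sample -> profiles
    groups: Dict[str, str]  # sample -> group label
    truth: pd.DataFrame  # locus id -> is_deh, target_a, target_b
    spec: SimulationSpec


def _truncated_poisson(rng: np.random.Generator, mean: float, floor: int, size: int) -> np.ndarray:
    cov = rng.poisson(mean, size=size)
    while (bad := cov < floor).any():
        cov[bad] = rng.poisson(mean, size=int(bad.sum()))
    return cov


def _dirichlet_rows(rng: np.random.Generator, alpha_rows: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws; zero concentrations give exact zeros."""
    g = rng.gamma(np.clip(alpha_rows, 0.0, None))
    return g / g.sum(axis=1, keepdims=True)


def simulate_profiles(spec: SimulationSpec) -> SimulatedCohort:
    """Generate per-sample epiallele profiles with planted DEH loci.

    The first ``round(deh_fraction * n_loci)`` loci are planted: group A
    sits at ``baseline_level`` of the chosen metric, group B at
    ``baseline_level + shift`` (group-level compositions calibrated
    exactly).  The rest are null loci sharing one composition drawn from
    Dirichlet(background_alpha) across both groups.  Ground-truth labels
    accompany the data.
    """
    rng = np.random.default_rng(spec.seed)
    n_deh = int(round(spec.deh_fraction * spec.n_loci))
    alpha0 = spec.resolved_alpha()
    level_a = spec.baseline_level
    level_b = spec.baseline_level + spec.shift

    loci, truth_rows = [], []
    pis = {g: [] for g in spec.group_names}
    for i in range(spec.n_loci):
        start = spec.locus_spacing * (i + 1)
        positions = tuple(start + spec.cpg_step * j for j in range(4))
        locus = LocusKey(spec.chrom, positions, "+")
        loci.append(locus)
        if i < n_deh:
            base = int(rng.choice([0, N_PATTERNS - 1]))
            pi_a = composition_for_metric(level_a, spec.metric, base)
            pi_b = composition_for_metric(level_b, spec.metric, base)
            truth_rows.append((locus.id, True, level_a, level_b))
        else:
            pi_a = pi_b = rng.dirichlet(np.full(N_PATTERNS, alpha0))
            truth_rows.append((locus.id, False, np.nan, np.nan))
        pis[spec.group_names[0]].append(pi_a)
        pis[spec.group_names[1]].append(pi_b)
    pi_mat = {g: np.asarray(v) for g, v in pis.items()}

    profiles: Dict[str, List[EpialleleProfile]] = {}
    groups: Dict[str, str] = {}
    kappa = spec.replicate_concentration
    for group, n in zip(spec.group_names, spec.n_samples):
        for k in range(n):
            sample = f"{group}_{k + 1:02d}"
            groups[sample] = group
            p = _dirichlet_rows(rng, kappa * pi_mat[group])
            coverage = _truncated_poisson(rng, spec.mean_coverage, spec.min_coverage, spec.n_loci)
            sample_profiles = []
            for i, locus in enumerate(loci):
                counts = rng.multinomial(coverage[i], p[i])
                sample_profiles.append(EpialleleProfile(locus, counts))
            profiles[sample] = sample_profiles
    truth = pd.DataFrame(
        truth_rows, columns=["locus", "is_deh", "target_a", "target_b"]
    ).set_index("locus")
    return SimulatedCohort(profiles, groups, truth, spec)


# ---------------------------------------------------------------------------
# Module cohort
# ---------------------------------------------------------------------------

@dataclass
class ModuleCohortSpec:
    """Study conditions for the planted-module matrix simulation."""

    seed: int
    n_samples: int = 12
    module_sizes: Tuple[int, ...] = (40, 40)
    n_background: int = 120
    loading: float = 1.0
    noise_sd: float = 0.1
    trait_module: int = 0
    trait_noise_sd: float = 0.1
    value_range: Tuple[float, float] = (0.0, EPIPOLY_MAX)

    def __post_init__(self):
        if self.seed is None:
            raise EpihetError("a seed is mandatory")
        if min(self.module_sizes, default=1) < 2 or self.n_samples < 3:
            raise EpihetError("module sizes must be >= 2 and n_samples >= 3")


@dataclass
class SimulatedModuleCohort:
    values: pd.DataFrame  # node x sample
    traits: pd.DataFrame  # sample x trait
    partition: pd.Series  # node -> planted label ("module<i>" or "grey")
    latent: pd.DataFrame  # module factor x sample
    spec: ModuleCohortSpec


def _squash(raw: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Logistic map of an unbounded score into the metric's valid range."""
    return lo + (hi - lo) / (1.0 + np.exp(-raw))


def simulate_module_cohort(spec: ModuleCohortSpec) -> SimulatedModuleCohort:
    """Generate a heterogeneity matrix with planted correlated node blocks.

    Members of module m take ``loading * z_m(sample) + noise`` where z_m is
    a standard-normal latent factor per sample; background nodes are
    independent noise.  Values are squashed into the metric range with a
    logistic map (correlation-preserving at moderate loadings).  One trait
    equals the designated module's factor plus noise.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{k + 1:02d}" for k in range(spec.n_samples)]
    factors = rng.normal(size=(len(spec.module_sizes), spec.n_samples))
    rows, labels, ids = [], [], []
    for m, size in enumerate(spec.module_sizes):
        raw = (
            spec.loading * factors[m][None, :]
            + rng.normal(scale=spec.noise_sd, size=(size, spec.n_samples))
        )
        rows.append(raw)
        ids.extend(f"MOD{m + 1}_N{j + 1:03d}" for j in range(size))
        labels.extend([f"module{m + 1}"] * size)
    if spec.n_background:
        rows.append(rng.normal(size=(spec.n_background, spec.n_samples)))
        ids.extend(f"BG_N{j + 1:03d}" for j in range(spec.n_background))
        labels.extend(["grey"] * spec.n_background)
    raw = np.vstack(rows)
    saturated = np.mean(np.abs(raw) > 3.0)
    if saturated > 0.5:
        logger.warning(
            "%.0f%% of simulated values lie in the saturated tail of the "
            "logistic squash; correlations will be attenuated", 100 * saturated,
        )
    lo, hi = spec.value_range
    values = pd.DataFrame(_squash(raw, lo, hi), index=ids, columns=samples)
    trait = factors[spec.trait_module] + rng.normal(
        scale=spec.trait_noise_sd, size=spec.n_samples
    )
    traits = pd.DataFrame({"trait": trait}, index=samples)
    partition = pd.Series(labels, index=ids, name="module")
    latent = pd.DataFrame(
        factors,
        index=[f"module{m + 1}" for m in range(len(spec.module_sizes))],
        columns=samples,
    )
    return SimulatedModuleCohort(values, traits, partition, latent, spec)


# ---------------------------------------------------------------------------
# SAM round-trip
# ---------------------------------------------------------------------------

def simulate_sam(
    profiles: Sequence[EpialleleProfile],
    sam_path: str,
    fasta_path: Optional[str] = None,
    read_length: int = 100,
    seed: int = 0,
) -> None:
    """Write a SAM file whose reads realize the given epiallele counts.

    Every read covers all four CpGs of its locus and carries a Bismark-style
    XM string with 'Z'/'z' at the CpG offsets; extraction with a matching
    configuration reproduces the input counts exactly.  Loci must not exceed
    the read length and (by the generators' construction) sit on disjoint
    spans.  A companion reference FASTA ('CG' at each CpG, 'A' elsewhere)
    is written when ``fasta_path`` is given.
    """
    rng = np.random.default_rng(seed)
    for p in profiles:
        if p.locus.span >= read_length:
            raise EpihetError(
                f"locus {p.locus.id} span {p.locus.span} does not fit in a "
                f"{read_length} bp read"
            )
    chrom_len: Dict[str, int] = {}
    for p in profiles:
        end = p.locus.positions[3] + read_length + 10
        chrom_len[p.locus.chrom] = max(chrom_len.get(p.locus.chrom, 0), end)

    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in sorted(chrom_len.items()):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        read_no = 0
        for prof in profiles:
            locus = prof.locus
            pad = min((read_length - locus.span - 1) // 2, locus.positions[0])
            start = locus.positions[0] - pad  # 0-based
            offsets = [p - start for p in locus.positions]
            flag = 16 if locus.strand == "-" else 0
            for code in range(N_PATTERNS):
                meth = [(code >> shift) & 1 for shift in (3, 2, 1, 0)]
                for _ in range(int(prof.counts[code])):
                    read_no += 1
                    seq = ["A"] * read_length
                    xm = ["."] * read_length
                    for off, m in zip(offsets, meth):
                        seq[off] = "C" if m else "T"
                        xm[off] = "Z" if m else "z"
                        if off + 1 < read_length:
                            seq[off + 1] = "G"
                    qual = "I" * read_length
                    fh.write(
                        f"read{read_no}\t{flag}\t{locus.chrom}\t{start + 1}\t42\t"
                        f"{read_length}M\t*\t0\t0\t{''.join(seq)}\t{qual}\t"
                        f"XM:Z:{''.join(xm)}\n"
                    )
    if fasta_path:
        with open(fasta_path, "w") as fh:
            cpgs: Dict[str, set] = {}
            for p in profiles:
                cpgs.setdefault(p.locus.chrom, set()).update(p.locus.positions)
            for chrom, length in sorted(chrom_len.items()):
                seq = np.full(length, "A", dtype="<U1")
                for pos in cpgs.get(chrom, ()):
                    seq[pos] = "C"
                    if pos + 1 < length:
                        seq[pos + 1] = "G"
                fh.write(f">{chrom}\n")
                s = "".join(seq)
                for i in range(0, length, 70):
                    fh.write(s[i : i + 70] + "\n")
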