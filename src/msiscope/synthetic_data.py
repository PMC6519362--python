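"""Synthetic control and CMMRD cohorts for every pipeline stage.

The generator mirrors the statistical structure the scorer assumes, layer by
layer, so each stage can be tested against known ground truth:

1. a *true* per-marker WT fraction per sample, drawn from marker-specific
   Beta distributions (controls) or the same Betas with a multiplicative
   depression applied (CMMRD);
2. a finite number of captured template molecules per marker (UMI families),
   so observed frequencies carry binomial sampling noise;
3. non-WT molecules offset from the reference length by -1/+1/-2/+2 bases,
   contraction-biased, matching polymerase slippage in homopolymers;
4. optionally, reads: each molecule amplified into a UMI family whose member
   reads independently suffer +-1 slippage miscalls.

Everything is driven by integer seeds through ``numpy.random.default_rng``;
identical (config, seed) gives byte-identical output files. What the
generator deliberately does not emulate: base-quality errors outside the
tract, chimeric reads, marker-specific capture bias beyond depth variation.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel_io import MarkerCounts, MarkerDefinition
from .read_processor import DEFAULT_MIN_MARKER_FAMILIES

__all__ = [
    "SimulationConfig",
    "synthetic_panel",
    "draw_wt_frequencies",
    "simulate_frequency_cohort",
    "simulate_fastq",
    "perturb_read_lengths",
]

_BASES = np.frombuffer(b"ACGT", np.uint8)

#: Length offsets carried by non-WT molecules and their relative weights:
#: 80% of variant mass at +-1, 20% at +-2, split toward contraction.
_VARIANT_OFFSETS = np.array([-1, +1, -2, +2])


def _variant_offset_probs(contraction_bias: float) -> np.ndarray:
    c = contraction_bias
    return np.array([0.8 * c, 0.8 * (1 - c), 0.2 * c, 0.2 * (1 - c)])


@dataclass
class SimulationConfig:
    """Generative parameters for synthetic cohorts.

    Defaults reproduce the assay's working point: 24 markers whose control
    WT-frequency means lie in 0.95-0.999 with concentrations of 50-300
    (Beta(60, 2)-like), a per-marker CMMRD depression of 2-15%, and a
    sequencing depth of 3,642 +- 1,659 reads per marker per sample split
    into UMI families of ~12 reads. Per-marker arrays left ``None`` are
    filled deterministically from ``seed``.
    """

    seed: int
    n_markers: int = 24
    control_alpha: np.ndarray | None = None
    control_beta: np.ndarray | None = None
    cmmrd_effect: np.ndarray | None = None
    mean_depth: float = 3642.0
    depth_sd: float = 1659.0
    min_depth: float = 200.0
    family_size_mean: float = 12.0
    families_per_marker: int | None = None
    per_read_length_error: float = 0.05
    contraction_bias: float = 0.7
    umi_length: int = 5

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ConfigError("n_markers must be positive")
        if not 0.0 <= self.per_read_length_error <= 1.0:
            raise ConfigError("per_read_length_error must lie in [0, 1]")
        if not 0.0 <= self.contraction_bias <= 1.0:
            raise ConfigError("contraction_bias must lie in [0, 1]")
        if self.mean_depth <= 0 or self.family_size_mean <= 0:
            raise ConfigError("depth and family size must be positive")
        rng = np.random.default_rng([int(self.seed), 0])
        mu = rng.uniform(0.95, 0.999, self.n_markers)
        kappa = rng.uniform(50.0, 300.0, self.n_markers)
        effect = rng.uniform(0.85, 0.98, self.n_markers)
        if self.control_alpha is None:
            self.control_alpha = mu * kappa
        if self.control_beta is None:
            self.control_beta = (1.0 - mu) * kappa
        if self.cmmrd_effect is None:
            self.cmmrd_effect = effect
        self.control_alpha = np.asarray(self.control_alpha, dtype=float)
        self.control_beta = np.asarray(self.control_beta, dtype=float)
        self.cmmrd_effect = np.asarray(self.cmmrd_effect, dtype=float)
        for name, arr in (
            ("control_alpha", self.control_alpha),
            ("control_beta", self.control_beta),
            ("cmmrd_effect", self.cmmrd_effect),
        ):
            if arr.shape != (self.n_markers,):
                raise ConfigError(f"{name} must have one entry per marker")
        if np.any(self.control_alpha <= 0) or np.any(self.control_beta <= 0):
            raise ConfigError("Beta parameters must be positive")
        if np.any((self.cmmrd_effect < 0) | (self.cmmrd_effect > 1)):
            raise ConfigError("cmmrd_effect entries must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic RNG stream derived from the config seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


def synthetic_panel(n_markers: int = 24, seed: int = 0) -> list[MarkerDefinition]:
    """A structurally valid stand-in panel (synthetic, not the published loci).

    Markers get wt_lengths cycling over 7-12, repeat units over A/C/G/T and
    random 10 bp flanks whose tract-facing bases are forced to differ from
    the repeat unit. Coordinates are laid out on a fictitious contig.
    """
    rng = np.random.default_rng([int(seed), 99])
    panel = []
    pos = 1000
    for i in range(n_markers):
        unit = "ACGT"[i % 4]
        wt = 7 + i % 6
        while True:
            left = bytes(rng.choice(_BASES, 10)).decode()
            right = bytes(rng.choice(_BASES, 10)).decode()
            if left[-1] != unit and right[0] != unit:
                break
        panel.append(
            MarkerDefinition(
                marker_id=f"M{i + 1:02d}",
                chrom="chrSim",
                start=pos,
                end=pos + wt,
                repeat_unit=unit,
                wt_length=wt,
                left_flank=left,
                right_flank=right,
            )
        )
        pos += wt + 500
    return panel


def draw_wt_frequencies(
    config: SimulationConfig,
    group: str,
    n_samples: int,
    rng: np.random.Generator,
    marker_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw true per-sample, per-marker WT fractions (samples x markers).

    Controls draw from Beta(alpha_m, beta_m); CMMRD samples draw from the
    same Beta and are multiplied by the marker's depression factor.
    """
    if group not in ("control", "cmmrd"):
        raise ConfigError(f"unknown group {group!r}")
    if n_samples < 1:
        raise ConfigError("cohort size must be positive")
    f = rng.beta(config.control_alpha, config.control_beta, size=(n_samples, config.n_markers))
    if group == "cmmrd":
        f = f * config.cmmrd_effect
    if marker_ids is None:
        marker_ids = [f"M{i + 1:02d}" for i in range(config.n_markers)]
    index = [f"{group}_{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(f, index=index, columns=list(marker_ids))


def _draw_family_counts(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Number of consensus families per marker, from depth or a fixed override."""
    if config.families_per_marker is not None:
        return np.maximum(rng.poisson(config.families_per_marker, n), 2)
    depth = rng.normal(config.mean_depth, config.depth_sd, n)
    depth = np.maximum(depth, config.min_depth)
    return np.maximum((depth / config.family_size_mean).round().astype(int), 2)


def simulate_frequency_cohort(
    config: SimulationConfig,
    group: str,
    n_samples: int,
    panel: Sequence[MarkerDefinition] | None = None,
    stream: int = 1,
    min_marker_families: int = DEFAULT_MIN_MARKER_FAMILIES,
) -> tuple[dict[str, list[MarkerCounts]], pd.DataFrame]:
    """Generate a cohort directly at the counts-table level.

    Per sample and marker: the true WT fraction is drawn, the family count is
    drawn around the configured depth, the WT family count is binomial at the
    true fraction and the non-WT families are spread over wt_length -1/+1/-2/+2
    (contraction-biased). Returns ``(samples, true_fractions)`` where the
    second element is the latent truth used to generate the first.
    """
    if panel is None:
        panel = synthetic_panel(config.n_markers, config.seed)
    if len(panel) != config.n_markers:
        raise ConfigError("panel size does not match n_markers")
    rng = config.rng(stream)
    truth = draw_wt_frequencies(
        config, group, n_samples, rng, marker_ids=[m.marker_id for m in panel]
    )
    offset_probs = _variant_offset_probs(config.contraction_bias)
    samples: dict[str, list[MarkerCounts]] = {}
    for sample_id, row in truth.iterrows():
        n_families = _draw_family_counts(config, config.n_markers, rng)
        counts = []
        for j, marker in enumerate(panel):
            total = int(n_families[j])
            wt = int(rng.binomial(total, row.iloc[j]))
            histogram = {marker.wt_length: wt} if wt else {}
            n_variant = total - wt
            if n_variant:
                split = rng.multinomial(n_variant, offset_probs)
                for offset, count in zip(_VARIANT_OFFSETS, split):
                    if count:
                        length = max(marker.wt_length + int(offset), 0)
                        histogram[length] = histogram.get(length, 0) + int(count)
            counts.append(
                MarkerCounts.from_histogram(
                    marker.marker_id, histogram, marker.wt_length, min_total=min_marker_families
                )
            )
        samples[str(sample_id)] = counts
    return samples, truth


def perturb_read_lengths(
    true_length: int,
    n_reads: int,
    per_read_length_error: float,
    contraction_bias: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the per-read slippage model: +-1 base with the configured bias."""
    lengths = np.full(n_reads, true_length, dtype=int)
    err = rng.random(n_reads) < per_read_length_error
    if err.any():
        step = np.where(rng.random(int(err.sum())) < contraction_bias, -1, +1)
        lengths[err] += step
    return np.maximum(lengths, 0)


def _random_umi(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(_BASES, length)).decode()


def simulate_fastq(
    config: SimulationConfig,
    sample_truth: Mapping[str, float] | pd.Series,
    panel: Sequence[MarkerDefinition],
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
    stream: int = 2,
) -> pd.DataFrame:
    """Write one sample's reads as FASTQ, plus the molecule-level truth table.

    Per marker: molecules are drawn with true lengths (WT with the sample's
    true fraction, otherwise slippage-offset variants), each molecule gets a
    uniform-random UMI (collisions possible and marked in the truth table),
    a family of reads whose sizes are Poisson around the configured mean,
    and every read's observed length is independently perturbed by the
    per-read slippage model. Reads are ``UMI + left_flank + tract +
    right_flank``. Gzipped output (by ``.gz`` suffix) is written with a fixed
    mtime so repeated runs are byte-identical.
    """
    rng = config.rng(stream)
    offset_probs = _variant_offset_probs(config.contraction_bias)
    truth_rows = []
    fastq_lines: list[str] = []
    read_no = 0
    for j, marker in enumerate(panel):
        f_true = float(sample_truth[marker.marker_id])
        n_molecules = int(_draw_family_counts(config, 1, rng)[0])
        is_wt = rng.random(n_molecules) < f_true
        offsets = rng.choice(_VARIANT_OFFSETS, size=n_molecules, p=offset_probs)
        true_lengths = np.where(is_wt, marker.wt_length, np.maximum(marker.wt_length + offsets, 0))
        sizes = rng.poisson(config.family_size_mean, n_molecules)
        sizes[sizes == 0] = 1
        umis = [_random_umi(rng, config.umi_length) for _ in range(n_molecules)]
        umi_counts: dict[str, int] = {}
        for u in umis:
            umi_counts[u] = umi_counts.get(u, 0) + 1
        for mol in range(n_molecules):
            tl = int(true_lengths[mol])
            lengths = perturb_read_lengths(
                tl, int(sizes[mol]), config.per_read_length_error, config.contraction_bias, rng
            )
            for ln in lengths:
                read_no += 1
                seq = umis[mol] + marker.left_flank + marker.repeat_unit * int(ln) + marker.right_flank
                fastq_lines += [f"@r{read_no}", seq, "+", "I" * len(seq)]
            truth_rows.append(
                {
                    "marker_id": marker.marker_id,
                    "umi": umis[mol],
                    "true_length": tl,
                    "family_size": int(sizes[mol]),
                    "umi_collision": umi_counts[umis[mol]] > 1,
                }
            )

    payload = ("\n".join(fastq_lines) + "\n").encode()
    fastq_path = Path(fastq_path)
    if fastq_path.suffix == ".gz":
        # fixed mtime and suppressed filename keep the archive byte-deterministic
        with open(fastq_path, "wb") as raw, gzip.GzipFile(
            filename="", fileobj=raw, mode="wb", mtime=0
        ) as fh:
            fh.write(payload)
    else:
        fastq_path.write_bytes(payload)

    truth = pd.DataFrame(truth_rows)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth
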