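"""Synthetic two-status genus count tables with known ground truth.

Emulates the sampling design of an environmental microbiome study of pig
farms: two groups of farms (high vs. low health status, HHS/LHS), a small
number of pooled surface or slurry samples per farm, and a genus-level
count table per sample type. Counts follow a log-normal relative-abundance
profile pushed through multinomial sampling at a Poisson-distributed
sequencing depth, with Bernoulli zero-inflation applied to the sampled
counts. A configurable subset of genera carries a between-status log-scale
shift; those genera and their signed effects are returned as ground truth
so that downstream selection and testing stages can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STATUSES = ("HHS", "LHS")
SAMPLE_TYPES = ("wall", "slat", "slurry")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study design.

    Attributes
    ----------
    n_farms_per_status:
        Farms per health-status group (the study design uses 3 + 3).
    n_pools_per_farm:
        Pooled samples taken per farm for one sample type (2 in the design).
    n_genera:
        Genera in the table; post-filter inventories in the motivating
        design are roughly 57 (wall), 95 (slat) and 259 (slurry).
    n_differential:
        Number of genera carrying a true between-status shift.
    effect_size:
        Between-status difference in mean log relative abundance, in units
        of the between-sample log-abundance SD (``overdispersion``).
    depth_mean:
        Mean sequencing depth (reads per sample); the realised depth is
        Poisson distributed. Default is desk-scale (10,000) rather than
        the ~100,000 reads of a full MiSeq run.
    zero_inflation:
        Probability that an observed count is structurally zeroed.
    overdispersion:
        SD of the per-sample log-abundance noise (natural-log scale).
    farm_sd_ratio:
        SD of the shared per-farm log-abundance perturbation, as a
        fraction of ``overdispersion``; makes pools from one farm
        correlated.
    n_stable_taxa:
        Number of abundant reference-like taxa whose between-sample noise
        is reduced to a quarter of ``overdispersion``. Real genus tables
        contain such low-variation taxa, and the downstream ALR
        preprocessing depends on one existing to serve as its reference;
        they never carry a differential effect.
    sample_type:
        Label written into the metadata ("wall", "slat" or "slurry").
    seed:
        Seed for all randomness; identical configs reproduce bit-identical
        tables.
    """

    n_farms_per_status: int = 3
    n_pools_per_farm: int = 2
    n_genera: int = 57
    n_differential: int = 10
    effect_size: float = 2.0
    depth_mean: int = 10_000
    zero_inflation: float = 0.05
    overdispersion: float = 1.0
    farm_sd_ratio: float = 0.25
    n_stable_taxa: int = 3
    sample_type: str = "wall"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_genera:
            raise ValueError(
                f"n_differential ({self.n_differential}) exceeds "
                f"n_genera ({self.n_genera})"
            )
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"sample_type must be one of {SAMPLE_TYPES}")
        if self.n_farms_per_status < 1 or self.n_pools_per_farm < 1:
            raise ValueError("need at least one farm and one pool per farm")
        if self.n_genera < 2:
            raise ValueError("need at least two genera")


@dataclass(frozen=True)
class GroundTruth:
    """Which genera truly differ between statuses, and in which direction.

    ``signed_effects`` maps genus id to the injected log-scale shift;
    positive values mean enrichment in HHS.
    """

    differential_genus_ids: frozenset[str]
    signed_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.signed_effects) != set(self.differential_genus_ids):
            raise ValueError("signed_effects keys must equal differential_genus_ids")


def _genus_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic dataset.

    Returns
    -------
    counts:
        DataFrame (samples x genera) of non-negative integers; index is
        sample id, columns are genus ids.
    metadata:
        DataFrame with columns ``sample_id``, ``status``, ``sample_type``,
        ``farm_id``, one row per sample.
    truth:
        :class:`GroundTruth` for the injected differential genera.
    """
    rng = np.random.default_rng(config.seed)
    genera = _genus_ids(config.n_genera)

    # Shared baseline log-abundance profile: a few dominant genera and a
    # long tail, as in real genus tables.
    baseline = rng.normal(0.0, 1.5, size=config.n_genera)

    # A few reference-like taxa with strongly reduced between-sample
    # noise. The ALR preprocessing downstream picks the lowest-CV genus
    # as its reference and relies on such a stable taxon existing — as it
    # does in real genus tables; with identical noise for every genus the
    # "reference" would be stable only by sampling luck, and its own
    # fluctuation would leak into every log-ratio.
    stability = np.ones(config.n_genera)
    abundant = np.flatnonzero(baseline >= np.median(baseline))
    stable_idx = rng.choice(
        abundant, size=min(config.n_stable_taxa, len(abundant)), replace=False
    )
    stability[stable_idx] = 0.25

    # Differential genera: random subset, alternating enrichment direction.
    # Drawn from above the 25th baseline percentile so the injected signal
    # is observable at the simulated depth (a shift on an ultra-rare genus
    # is censored to zeros in the depleted group).
    if config.effect_size != 0.0 and config.n_differential > 0:
        pool = np.flatnonzero(baseline >= np.quantile(baseline, 0.25))
        pool = np.setdiff1d(pool, stable_idx)  # stable taxa are never differential
        if config.n_differential > len(pool):
            raise ValueError(
                "n_differential exceeds the abundant-genus pool "
                f"({len(pool)} of {config.n_genera} genera)"
            )
        diff_idx = rng.choice(pool, size=config.n_differential, replace=False)
        signs = np.where(np.arange(config.n_differential) % 2 == 0, 1.0, -1.0)
        rng.shuffle(signs)
        effects = signs * config.effect_size * config.overdispersion
        truth = GroundTruth(
            differential_genus_ids=frozenset(genera[i] for i in diff_idx),
            signed_effects={
                genera[i]: float(e) for i, e in zip(diff_idx, effects)
            },
        )
    else:
        diff_idx = np.empty(0, dtype=int)
        effects = np.empty(0)
        truth = GroundTruth(differential_genus_ids=frozenset())

    shift = np.zeros(config.n_genera)
    shift[diff_idx] = effects / 2.0  # +e/2 in HHS, -e/2 in LHS

    rows, meta_rows = [], []
    farm_sd = config.farm_sd_ratio * config.overdispersion
    for status in STATUSES:
        status_sign = 1.0 if status == "HHS" else -1.0
        for farm in range(1, config.n_farms_per_status + 1):
            farm_id = f"{status}_farm{farm}"
            farm_effect = rng.normal(0.0, farm_sd, size=config.n_genera) * stability
            for pool in range(1, config.n_pools_per_farm + 1):
                noise = (
                    rng.normal(0.0, config.overdispersion, config.n_genera)
                    * stability
                )
                log_abund = baseline + status_sign * shift + farm_effect + noise
                props = np.exp(log_abund - log_abund.max())
                props /= props.sum()
                depth = max(int(rng.poisson(config.depth_mean)), 1)
                counts = rng.multinomial(depth, props)
                if config.zero_inflation > 0.0:
                    keep_from_zeroing = counts.argmax()
                    mask = rng.random(config.n_genera) < config.zero_inflation
                    mask[keep_from_zeroing] = False  # keep row sums positive
                    counts = np.where(mask, 0, counts)
                rows.append(counts)
                meta_rows.append(
                    {
                        "sample_id": f"{farm_id}_{config.sample_type}_p{pool}",
                        "status": status,
                        "sample_type": config.sample_type,
                        "farm_id": farm_id,
                    }
                )

    metadata = pd.DataFrame(meta_rows)
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index(metadata["sample_id"], name="sample_id"),
        columns=genera,
    )
    return counts, metadata, truth


def write_dataset(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: GroundTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write counts / metadata / ground truth as TSV; returns the paths.

    The counts file has samples as rows (first column ``sample_id``) and
    genera as columns; the ground-truth file has columns ``genus_id`` and
    ``effect`` (header only when no genus is differential).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "ground_truth.tsv",
    }
    counts.to_csv(paths["counts"], sep="\t")
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    truth_df = pd.DataFrame(
        sorted(truth.signed_effects.items()), columns=["genus_id", "effect"]
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a ground-truth TSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t", dtype={"genus_id": str})
    effects = {
        str(g): float(e) for g, e in zip(df["genus_id"], df["effect"])
    }
    return GroundTruth(
        differential_genus_ids=frozenset(effects), signed_effects=effects
    )
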