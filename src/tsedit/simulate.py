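"""Synthetic editing datasets with known tissue-specific structure.

The generator emulates the three pipeline inputs — a site catalog, a
library table, and per-sequence base observations — with a binomial model
of editing: at every (site, library) pair, each of ``obs_per_site_per_library``
expressed sequences is independently edited with probability equal to the
tissue-specific effect rate when (site, tissue-of-library) carries an
effect, and ``background_rate`` otherwise.  Observations are emitted as
plus-strand base letters honoring site strand (an edited transcript reads G
on a plus-strand site and C on a minus-strand site), so the downstream
classifier path is always exercised.  Decoy libraries annotated "mixed" or
"" exercise both library-exclusion rules and are generated at background
rate.

All randomness flows from one :func:`numpy.random.default_rng` stream
seeded by ``config.seed``: identical configs give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    EditingSite,
    LibraryRecord,
    write_libraries,
    write_observations,
    write_sites,
)


class ConfigurationError(ValueError):
    """An invalid simulation configuration, naming the offending field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of one synthetic dataset.

    ``effects`` lists (site_index, tissue_index, rate) triples giving the
    editing level in that tissue; everywhere else the level is
    ``background_rate``.  ``coverage_multipliers``, when given, scales the
    per-library sequence count tissue by tissue (real EST coverage is highly
    uneven across tissues; the default is uniform).
    """

    n_tissues: int
    libraries_per_tissue: int
    n_sites: int
    obs_per_site_per_library: int
    background_rate: float
    effects: tuple[tuple[int, int, float], ...] = ()
    n_decoy_libraries: int = 0
    seed: int = 0
    coverage_multipliers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("n_tissues", "libraries_per_tissue", "n_sites"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.obs_per_site_per_library < 0:
            raise ConfigurationError("obs_per_site_per_library must be >= 0")
        if self.n_decoy_libraries < 0:
            raise ConfigurationError("n_decoy_libraries must be >= 0")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ConfigurationError("background_rate must lie in [0, 1]")
        for site_i, tissue_i, rate in self.effects:
            if not 0 <= site_i < self.n_sites:
                raise ConfigurationError(f"effects: site index {site_i} out of range")
            if not 0 <= tissue_i < self.n_tissues:
                raise ConfigurationError(f"effects: tissue index {tissue_i} out of range")
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"effects: rate {rate} outside [0, 1]")
        if self.coverage_multipliers is not None:
            if len(self.coverage_multipliers) != self.n_tissues:
                raise ConfigurationError(
                    "coverage_multipliers must have one entry per tissue"
                )
            if any(m < 0 for m in self.coverage_multipliers):
                raise ConfigurationError("coverage_multipliers must be non-negative")


@dataclass
class SyntheticDataset:
    """Generated sites, libraries, observations and the ground truth.

    ``observations`` follows the :class:`tsedit.io.SiteObservation` column
    schema plus an ``edited`` truth column (dropped when written to file).
    ``truth`` lists the (site, tissue_name) pairs whose effect rate differs
    from the background — the pairs a perfect detector would call.
    """

    config: SimulationConfig
    sites: list[EditingSite]
    libraries: list[LibraryRecord]
    observations: pd.DataFrame
    truth: list[tuple[EditingSite, str]] = field(default_factory=list)


def tissue_name(index: int) -> str:
    return f"tissue{index:02d}"


def _make_sites(n_sites: int) -> list[EditingSite]:
    # alternate strands so both classifier paths are exercised
    return [
        EditingSite(
            chrom=f"chr{(i % 22) + 1}",
            strand="+" if i % 2 == 0 else "-",
            position=1000 * (i + 1) + 1,
            gene=f"GENE{i}",
        )
        for i in range(n_sites)
    ]


def _make_libraries(config: SimulationConfig) -> tuple[list[LibraryRecord], list[int]]:
    """Return libraries plus, per library, its tissue index (-1 for decoys)."""
    libraries: list[LibraryRecord] = []
    tissue_idx: list[int] = []
    for t in range(config.n_tissues):
        for j in range(config.libraries_per_tissue):
            libraries.append(LibraryRecord(f"LIB{t:02d}_{j:02d}", tissue_name(t)))
            tissue_idx.append(t)
    for k in range(config.n_decoy_libraries):
        annotation = "mixed" if k % 2 == 0 else ""
        libraries.append(LibraryRecord(f"DECOY{k:02d}", annotation))
        tissue_idx.append(-1)
    return libraries, tissue_idx


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset under the binomial editing model."""
    rng = np.random.default_rng(config.seed)
    sites = _make_sites(config.n_sites)
    libraries, lib_tissue = _make_libraries(config)

    effect_rate = {(s, t): r for s, t, r in config.effects}
    n_libs = len(libraries)

    # per-(site, library) editing probability and coverage
    rates = np.full((config.n_sites, n_libs), config.background_rate)
    for (s, t), r in effect_rate.items():
        for j, ti in enumerate(lib_tissue):
            if ti == t:
                rates[s, j] = r
    coverage = np.full(n_libs, config.obs_per_site_per_library, dtype=int)
    if config.coverage_multipliers is not None:
        for j, ti in enumerate(lib_tissue):
            if ti >= 0:
                coverage[j] = int(
                    round(config.obs_per_site_per_library * config.coverage_multipliers[ti])
                )

    records: dict[str, list] = {c: [] for c in
                                ("sequence_id", "library_id", "chrom", "strand",
                                 "position", "observed_base_plus", "edited")}
    for si, site in enumerate(sites):
        edited_base = "G" if site.strand == "+" else "C"
        unedited_base = "A" if site.strand == "+" else "T"
        for j, lib in enumerate(libraries):
            n = int(coverage[j])
            if n == 0:
                continue
            k = int(rng.binomial(n, rates[si, j]))
            flags = [True] * k + [False] * (n - k)
            records["sequence_id"].extend(
                f"EST_s{si}_{lib.library_id}_{i}" for i in range(n)
            )
            records["library_id"].extend([lib.library_id] * n)
            records["chrom"].extend([site.chrom] * n)
            records["strand"].extend([site.strand] * n)
            records["position"].extend([site.position] * n)
            records["observed_base_plus"].extend(
                edited_base if f else unedited_base for f in flags
            )
            records["edited"].extend(flags)
    observations = pd.DataFrame(records)
    if observations.empty:
        observations = pd.DataFrame(
            columns=["sequence_id", "library_id", "chrom", "strand", "position",
                     "observed_base_plus", "edited"]
        )
    observations["gene"] = (
        observations["position"].map({s.position: s.gene for s in sites})
        if len(observations)
        else None
    )

    truth = [
        (sites[s], tissue_name(t))
        for s, t, r in config.effects
        if r != config.background_rate
    ]
    return SyntheticDataset(config, sites, libraries, observations, truth)


def generate_null_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a fully-null dataset (uniform background rate, empty truth)."""
    if config.effects:
        raise ConfigurationError("a null dataset requires config.effects to be empty")
    return generate_dataset(config)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write sites/libraries/observations/truth TSVs readable by tsedit.io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": outdir / "sites.tsv",
        "libraries": outdir / "libraries.tsv",
        "observations": outdir / "observations.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_sites(dataset.sites, paths["sites"])
    write_libraries(dataset.libraries, paths["libraries"])
    write_observations(dataset.observations, paths["observations"])
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tstrand\tposition\ttissue\n")
        for site, tissue in dataset.truth:
            fh.write(f"{site.chrom}\t{site.strand}\t{site.position}\t{tissue}\n")
    return paths
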