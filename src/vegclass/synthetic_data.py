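"""Labeled synthetic relevé data with the structure the analysis assumes.

Real national vegetation-plot databases cannot be redistributed, so this
module generates relevé tables that emulate their structure: one
:class:`UnitProfile` per vegetation unit draws core species (the unit's
diagnostic set, at high occurrence probability and covers that satisfy the
packaged formal definitions), unit companions, and a background pool of
common wetland companions shared across all units (so fidelity statistics
face realistic shared species).  Covers are log-uniform (ephemeral
vegetation has many low covers and few dominants), coordinates are Gaussian
around unit-specific centers inside Poland's bounding box (so geographic
strata are non-trivial), and plot areas are uniform on 1–100 m².

The emulation is structural, not distributional: species-richness and
cover distributions of real archives are not matched, so passing tests
demonstrate correctness of the machinery, not field performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .releve_io import Releve, ReleveTable, DEFAULT_LAYER

__all__ = [
    "SpeciesSpec",
    "UnitProfile",
    "SyntheticDataset",
    "BACKGROUND_POOL",
    "default_profiles",
    "generate",
    "gradient_matrix",
    "perturb",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """Occurrence probability and log-uniform cover range (percent)."""

    taxon: str
    prob: float
    cover_lo: float
    cover_hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"{self.taxon}: probability outside [0, 1]")
        if not 0.0 < self.cover_lo <= self.cover_hi <= 100.0:
            raise ValueError(f"{self.taxon}: cover bounds outside (0, 100]")


@dataclass(frozen=True)
class UnitProfile:
    """Assemblage recipe for one vegetation unit."""

    name: str
    alliance: str
    core: tuple[SpeciesSpec, ...]
    companions: tuple[SpeciesSpec, ...] = ()
    n_plots: int = 50
    center: tuple[float, float] = (19.0, 52.0)  # lon, lat degrees
    scatter: float = 0.35  # Gaussian sd, degrees
    area_range: tuple[float, float] = (1.0, 100.0)
    rank: str = "association"

    @property
    def core_taxa(self) -> tuple[str, ...]:
        return tuple(s.taxon for s in self.core)


def _spec(taxon: str, prob: float, lo: float, hi: float) -> SpeciesSpec:
    return SpeciesSpec(taxon, prob, lo, hi)


#: Frequent companions shared across all units (kept below the class
#: total-cover threshold so background alone never satisfies a definition).
BACKGROUND_POOL: tuple[SpeciesSpec, ...] = (
    _spec("Juncus bufonius", 0.60, 1, 15),
    _spec("Gnaphalium uliginosum", 0.50, 1, 10),
    _spec("Plantago major subsp. intermedia", 0.40, 1, 10),
    _spec("Rorippa palustris", 0.30, 1, 10),
    _spec("Agrostis stolonifera", 0.30, 1, 15),
    _spec("Polygonum aviculare s. l.", 0.25, 1, 10),
    _spec("Sagina procumbens", 0.20, 1, 10),
    _spec("Persicaria hydropiper", 0.20, 1, 10),
    _spec("Persicaria lapathifolia s. l.", 0.20, 1, 10),
    _spec("Rumex acetosella", 0.20, 1, 10),
    _spec("Spergula arvensis", 0.20, 1, 10),
    _spec("Rumex maritimus", 0.15, 1, 10),
    _spec("Bidens tripartitus", 0.15, 1, 10),
    _spec("Oxybasis rubra", 0.15, 1, 10),
    _spec("Mentha arvensis", 0.15, 1, 10),
    _spec("Alisma plantago-aquatica", 0.15, 1, 10),
    _spec("Equisetum arvense", 0.15, 1, 5),
    _spec("Atriplex prostrata", 0.10, 1, 5),
    _spec("Argentina anserina", 0.10, 1, 5),
    _spec("Scleranthus annuus", 0.10, 1, 5),
)


def default_profiles() -> list[UnitProfile]:
    """One profile per published vegetation unit (14 units in 3 alliances).

    Core species are each unit's diagnostic species — the members of its
    sociological group, or its dominant diagnostic species for units defined
    by a 25 % single-species dominance clause — with plot counts defaulting
    to the published unit sizes.  Geographic centers follow the reported
    regional concentrations.
    """
    E, V, R = "Eleocharition soloniensis", "Verbenion supinae", "Radiolion linoidis"
    return [
        UnitProfile(
            name="Polygono-Eleocharitetum ovatae",
            alliance=E, n_plots=129, center=(16.9, 51.1),
            core=(
                _spec("Eleocharis ovata", 0.95, 15, 80),
                _spec("Carex bohemica", 0.90, 15, 70),
                _spec("Lindernia procumbens", 0.85, 15, 70),
            ),
            companions=(
                _spec("Eleocharis acicularis", 0.60, 5, 40),
                _spec("Elatine triandra", 0.30, 5, 30),
            ),
        ),
        UnitProfile(
            name="Cypero fusci-Limoselletum aquaticae",
            alliance=E, n_plots=127, center=(15.5, 52.3),
            core=(
                _spec("Cyperus fuscus", 0.95, 15, 80),
                _spec("Limosella aquatica", 0.90, 15, 70),
                _spec("Potentilla supina", 0.80, 15, 50),
            ),
            companions=(_spec("Eleocharis acicularis", 0.40, 5, 30),),
        ),
        UnitProfile(
            name="Cyperetum micheliani",
            alliance=E, n_plots=4, center=(16.1, 51.66), scatter=0.05,
            core=(_spec("Cyperus michelianus", 1.0, 30, 90),),
            companions=(
                _spec("Cyperus fuscus", 0.60, 5, 20),
                _spec("Limosella aquatica", 0.50, 5, 20),
            ),
        ),
        UnitProfile(
            name="Community with Coleanthus subtilis",
            alliance=E, n_plots=12, center=(16.3, 51.3), scatter=0.15,
            rank="community",
            core=(_spec("Coleanthus subtilis", 1.0, 30, 90),),
            companions=(
                _spec("Veronica peregrina", 0.70, 5, 30),
                _spec("Myosurus minimus", 0.50, 5, 20),
                _spec("Limosella aquatica", 0.50, 5, 20),
                _spec("Riccia cavernosa", 0.50, 5, 20),
            ),
        ),
        UnitProfile(
            name="Veronico anagalloidis-Lythretum hyssopifoliae",
            alliance=V, n_plots=3, center=(18.0, 52.3), scatter=0.8,
            core=(_spec("Juncus ranarius", 1.0, 30, 90),),
            companions=(_spec("Juncus compressus", 0.50, 2, 15),),
        ),
        UnitProfile(
            name="Cyperetum flavescentis",
            alliance=V, n_plots=8, center=(22.5, 50.5), scatter=0.3,
            core=(
                _spec("Cyperus flavescens", 1.0, 30, 90),
                _spec("Sagina nodosa", 0.60, 5, 30),
            ),
            companions=(
                _spec("Ranunculus flammula", 0.40, 2, 15),
                _spec("Juncus articulatus", 0.40, 2, 15),
            ),
        ),
        UnitProfile(
            name="Pulicario vulgaris-Menthetum pulegii",
            alliance=V, n_plots=19, center=(15.8, 52.0), scatter=0.4,
            core=(
                _spec("Pulicaria vulgaris", 1.0, 30, 90),
                _spec("Mentha pulegium", 0.60, 5, 30),
            ),
        ),
        UnitProfile(
            name="Eleocharito-Schoenoplectetum supini",
            alliance=V, n_plots=16, center=(23.0, 51.0), scatter=0.3,
            core=(
                _spec("Elatine alsinastrum", 0.92, 20, 80),
                _spec("Schoenoplectus supinus", 0.92, 20, 70),
                _spec("Alisma lanceolatum", 0.85, 5, 40),
            ),
            companions=(_spec("Lythrum hyssopifolia", 0.50, 5, 30),),
        ),
        UnitProfile(
            name="Stellario uliginosae-Isolepidetum setaceae",
            alliance=R, n_plots=20, center=(15.2, 51.8), scatter=0.4,
            core=(
                _spec("Isolepis setacea", 0.95, 30, 90),
                _spec("Juncus tenageia", 0.85, 10, 50),
                _spec("Stellaria alsine", 0.85, 10, 50),
            ),
        ),
        UnitProfile(
            name="Centunculo minimi-Anthoceretum punctati",
            alliance=R, n_plots=90, center=(21.0, 51.5), scatter=0.5,
            core=(
                _spec("Anagallis minima", 0.90, 15, 70),
                _spec("Anthoceros punctatus s. l.", 0.85, 15, 60),
                _spec("Radiola linoides", 0.85, 15, 60),
                _spec("Juncus capitatus", 0.60, 10, 40),
            ),
        ),
        UnitProfile(
            name="Hyperico humifusi-Spergularietum rubrae",
            alliance=R, n_plots=42, center=(22.0, 50.8), scatter=0.4,
            core=(
                _spec("Spergularia rubra", 0.95, 15, 70),
                _spec("Gypsophila muralis", 0.95, 15, 70),
                _spec("Hypericum humifusum", 0.80, 10, 50),
                _spec("Laphangium luteoalbum", 0.60, 5, 30),
            ),
        ),
        UnitProfile(
            name="Panico-Illecebretum verticillati",
            alliance=R, n_plots=47, center=(19.5, 50.5), scatter=0.4,
            core=(_spec("Illecebrum verticillatum", 1.0, 30, 90),),
            companions=(
                _spec("Spergularia rubra", 0.50, 5, 25),
                _spec("Hypericum humifusum", 0.40, 5, 25),
                _spec("Radiola linoides", 0.40, 5, 25),
                _spec("Teesdalia nudicaulis", 0.40, 2, 15),
            ),
        ),
        UnitProfile(
            name="Cerastio dubii-Ranunculetum sardoi",
            alliance=R, n_plots=9, center=(17.5, 52.8), scatter=0.6,
            core=(
                _spec("Ranunculus sardous", 0.95, 30, 90),
                _spec("Myosurus minimus", 0.90, 10, 50),
                _spec("Bryum ruderale", 0.75, 5, 30),
            ),
        ),
        UnitProfile(
            name="Community with Montia arvensis",
            alliance=R, n_plots=15, center=(15.0, 52.2), scatter=0.2,
            rank="community",
            core=(_spec("Montia arvensis", 1.0, 30, 90),),
            companions=(
                _spec("Myosurus minimus", 0.60, 5, 25),
                _spec("Riccia sorocarpa", 0.50, 5, 25),
            ),
        ),
    ]


@dataclass
class SyntheticDataset:
    """A generated relevé table with its true per-plot unit labels."""

    table: ReleveTable
    labels: dict[str, str]
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def alliances(self) -> dict[str, str]:
        return dict(self.config.get("alliances", {}))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate(
    profiles: Sequence[UnitProfile] | None = None,
    n_per_unit: int | None = None,
    seed: int = 0,
    background: Sequence[SpeciesSpec] = BACKGROUND_POOL,
) -> SyntheticDataset:
    """Generate a labeled dataset, deterministic under *seed*.

    *n_per_unit* overrides every profile's plot count (useful for balanced
    experiments); by default each profile's own (published-size) count is
    used.
    """
    profiles = list(default_profiles() if profiles is None else profiles)
    rng = np.random.default_rng(seed)
    releves, labels = [], {}
    for ui, prof in enumerate(profiles):
        n = prof.n_plots if n_per_unit is None else n_per_unit
        for i in range(n):
            plot_id = f"u{ui + 1:02d}_{i + 1:04d}"
            records = {}
            for spec in (*prof.core, *prof.companions, *background):
                if rng.random() < spec.prob:
                    cover = _log_uniform(rng, spec.cover_lo, spec.cover_hi) / 100.0
                    records[(spec.taxon, DEFAULT_LAYER)] = cover
            lon = float(rng.normal(prof.center[0], prof.scatter))
            lat = float(rng.normal(prof.center[1], prof.scatter))
            area = float(rng.uniform(*prof.area_range))
            releves.append(
                Releve(plot_id, records, lon=lon, lat=lat, area=area)
            )
            labels[plot_id] = prof.name
    config = {
        "n_per_unit": n_per_unit,
        "units": [p.name for p in profiles],
        "alliances": {p.name: p.alliance for p in profiles},
        "ranks": {p.name: p.rank for p in profiles},
        "core_taxa": {p.name: list(p.core_taxa) for p in profiles},
    }
    return SyntheticDataset(
        table=ReleveTable(releves), labels=labels, seed=seed, config=config
    )


def perturb(
    dataset: SyntheticDataset,
    dropout: float = 0.0,
    cover_jitter: float = 0.0,
    background_fraction: float = 0.0,
    seed: int = 0,
    background: Sequence[SpeciesSpec] = BACKGROUND_POOL,
    background_label: str = "background",
) -> SyntheticDataset:
    """Degrade a dataset: random record deletion, multiplicative cover
    jitter (log-normal, sd *cover_jitter*), and injection of plots drawn
    from the background pool only (labeled *background_label*; they should
    classify at class/alliance level or not at all)."""
    for rate in (dropout, background_fraction):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    releves, labels = [], {}
    for rel in dataset.table:
        records = {}
        for key, cover in rel.records.items():
            if dropout and rng.random() < dropout:
                continue
            if cover_jitter:
                cover = min(1.0, cover * float(np.exp(rng.normal(0, cover_jitter))))
            records[key] = cover
        releves.append(replace(rel, records=records))
        labels[rel.plot_id] = dataset.labels[rel.plot_id]
    n_extra = int(round(background_fraction * len(dataset.table)))
    for i in range(n_extra):
        plot_id = f"bg_{i + 1:04d}"
        records = {}
        while not records:
            records = {
                (spec.taxon, DEFAULT_LAYER): _log_uniform(
                    rng, spec.cover_lo, spec.cover_hi
                ) / 100.0
                for spec in background
                if rng.random() < spec.prob
            }
        releves.append(
            Releve(
                plot_id,
                records,
                lon=float(rng.uniform(14.2, 24.0)),
                lat=float(rng.uniform(49.1, 54.7)),
                area=float(rng.uniform(1, 100)),
            )
        )
        labels[plot_id] = background_label
    config = dict(dataset.config)
    config["perturb"] = {
        "dropout": dropout,
        "cover_jitter": cover_jitter,
        "background_fraction": background_fraction,
    }
    return SyntheticDataset(
        table=ReleveTable(releves), labels=labels, seed=seed, config=config
    )


def gradient_matrix(
    n_plots: int = 50,
    n_species: int = 20,
    sd: float = 0.15,
    max_abundance: float = 50.0,
) -> pd.DataFrame:
    """Noise-free coenocline: Gaussian species responses along one gradient.

    Plots sit evenly on a unit gradient and species optima are evenly
    spaced, so the gradient order is the ground truth for ordination
    axis-1 order.
    """
    x = np.linspace(0.0, 1.0, n_plots)
    optima = np.linspace(0.0, 1.0, n_species)
    ab = max_abundance * np.exp(-((x[:, None] - optima[None, :]) ** 2) / (2 * sd**2))
    ab[ab < 1e-6] = 0.0
    return pd.DataFrame(
        ab,
        index=[f"p{i+1:03d}" for i in range(n_plots)],
        columns=[f"sp{j+1:02d}" for j in range(n_species)],
    )
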