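"""Fidelity statistics and synoptic tables.

Fidelity of a species to a vegetation unit is measured by the phi
coefficient of the 2x2 presence table (unit membership x species
occurrence), with significance from a one-sided Fisher exact test
(over-representation).  A synoptic table holds, per (unit, species),
percentage frequency (constancy), phi, Fisher p and the species-role flags:

* diagnostic   — phi >= rank threshold (0.20 alliance / 0.25 association),
                 p < 0.001, and the species is on the preselected class list;
* differential — same phi/p test but the species is not on the class list;
* constant     — frequency >= 40 % of the unit's relevés;
* dominant     — cover >= 25 % in >= 5 % of the unit's relevés.

Phi is computed on presence/absence over the pooled analysed data set (the
unit against all remaining relevés); no group-size standardization is
applied by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import hypergeom

from .releve_io import ReleveTable, name_key

__all__ = [
    "FidelityInput",
    "RoleThresholds",
    "SynopticTable",
    "build_synoptic",
    "class_species_list",
    "fisher_one_sided",
    "phi",
    "species_roles",
]


@dataclass(frozen=True)
class FidelityInput:
    """2x2 counts: N relevés total, N_p in the unit, n containing the
    species, n_p in the unit containing the species."""

    N: int
    N_p: int
    n: int
    n_p: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.n_p <= min(self.n, self.N_p)
            and self.N_p <= self.N
            and self.n <= self.N
            and self.n - self.n_p <= self.N - self.N_p
        )
        if not ok:
            raise ValueError(f"inconsistent 2x2 counts: {self}")


def phi(fi: FidelityInput) -> float:
    """Phi coefficient of association between species and unit, in [-1, 1].

    ``(N*n_p - n*N_p) / sqrt(n*N_p*(N-n)*(N-N_p))``; 0 by convention when
    the denominator vanishes (species everywhere or nowhere, unit empty or
    universal).
    """
    denom = fi.n * fi.N_p * (fi.N - fi.n) * (fi.N - fi.N_p)
    if denom == 0:
        return 0.0
    return (fi.N * fi.n_p - fi.n * fi.N_p) / math.sqrt(denom)


def fisher_one_sided(fi: FidelityInput) -> float:
    """One-sided Fisher exact p for over-representation: P(X >= n_p) with X
    hypergeometric (population N, successes N_p, draws n)."""
    return float(hypergeom.sf(fi.n_p - 1, fi.N, fi.N_p, fi.n))


def class_species_list(path: str | Path | None = None) -> frozenset[str]:
    """Matching keys of the preselected class diagnostic-species list (the
    members of the packaged class total-cover group)."""
    from .cocktail_engine import load_groups

    groups = load_groups(path)
    for g in groups:
        if g.kind == "TC" and g.name == "Isoeto-Nanojuncetea":
            return g.member_keys
    raise ValueError("class total-cover group not found")


@dataclass(frozen=True)
class RoleThresholds:
    """Thresholds of the species-role rules (boundary semantics as printed:
    phi uses >=, p strict <, constancy >=, dominance cover >= and
    frequency >=)."""

    phi_alliance: float = 0.20
    phi_association: float = 0.25
    p_max: float = 0.001
    constancy_min: float = 40.0  # percent frequency
    dominance_cover: float = 25.0  # percent cover
    dominance_freq: float = 5.0  # percent of the unit's relevés
    class_species: frozenset[str] = field(default_factory=class_species_list)

    def phi_for_rank(self, rank: str) -> float:
        # class-rank units use the (laxer) alliance threshold
        return self.phi_association if rank == "association" else self.phi_alliance


@dataclass
class SynopticTable:
    """Per-(unit, species) frequency, fidelity and significance.

    All stat frames are species x units; ``roles`` (filled by
    :func:`species_roles`) holds frozensets of role names.
    """

    frequency: pd.DataFrame  # percent
    phi: pd.DataFrame
    fisher_p: pd.DataFrame
    n_plots: dict[str, int]
    roles: pd.DataFrame | None = None

    @property
    def units(self) -> list[str]:
        return list(self.frequency.columns)

    @property
    def species(self) -> list[str]:
        return list(self.frequency.index)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: unit, species, freq (1 decimal), phi, p, roles."""
        rows = []
        for unit in self.units:
            for sp in self.species:
                freq = self.frequency.at[sp, unit]
                if freq == 0 and (
                    self.roles is None or not self.roles.at[sp, unit]
                ):
                    continue
                rows.append(
                    {
                        "unit": unit,
                        "species": sp,
                        "freq": round(float(freq), 1),
                        "phi": float(self.phi.at[sp, unit]),
                        "p": float(self.fisher_p.at[sp, unit]),
                        "roles": ";".join(
                            sorted(self.roles.at[sp, unit])
                        ) if self.roles is not None else "",
                    }
                )
        return pd.DataFrame(rows, columns=["unit", "species", "freq", "phi", "p", "roles"])


def _presence(table: ReleveTable) -> pd.DataFrame:
    """Plots x species boolean presence matrix (layer-pooled)."""
    species = sorted(table.taxa)
    data = np.zeros((len(table), len(species)), dtype=bool)
    col = {sp: j for j, sp in enumerate(species)}
    for i, rel in enumerate(table):
        for t in rel.taxa:
            data[i, col[t]] = True
    return pd.DataFrame(data, index=table.plot_ids, columns=species)


def build_synoptic(table: ReleveTable, labels: Mapping[str, str]) -> SynopticTable:
    """Build a combined synoptic table over the labeled plots.

    The fidelity universe is the set of labeled plots, all units pooled; phi
    for a unit contrasts that unit against all remaining labeled relevés.
    """
    for plot_id in labels:
        if plot_id not in table:
            raise ValueError(f"labeled plot {plot_id!r} not in table")
    sub = table.subset(sorted(labels))
    units = sorted(set(labels.values()))
    pres = _presence(sub)
    N = len(sub)
    n = pres.to_numpy().sum(axis=0)  # per species

    freq = {}
    phis = {}
    pvals = {}
    for unit in units:
        mask = np.array([labels[p] == unit for p in pres.index])
        N_p = int(mask.sum())
        if N_p == 0:
            raise ValueError(f"unit {unit!r} has 0 plots")
        n_p = pres.to_numpy()[mask].sum(axis=0)
        freq[unit] = 100.0 * n_p / N_p
        denom = n * N_p * (N - n) * (N - N_p)
        with np.errstate(invalid="ignore", divide="ignore"):
            ph = np.where(
                denom > 0, (N * n_p - n * N_p) / np.sqrt(np.maximum(denom, 1)), 0.0
            )
        phis[unit] = ph
        pvals[unit] = hypergeom.sf(n_p - 1, N, N_p, n)

    species = list(pres.columns)
    return SynopticTable(
        frequency=pd.DataFrame(freq, index=species),
        phi=pd.DataFrame(phis, index=species),
        fisher_p=pd.DataFrame(pvals, index=species),
        n_plots={
            unit: int(sum(1 for u in labels.values() if u == unit)) for unit in units
        },
    )


def species_roles(
    syn: SynopticTable,
    table: ReleveTable,
    labels: Mapping[str, str],
    thresholds: RoleThresholds | None = None,
    ranks: Mapping[str, str] | None = None,
) -> SynopticTable:
    """Assign diagnostic/differential/constant/dominant flags.

    *ranks* maps each unit to its rank ("alliance" or "association"); units
    missing from it default to "association".  Role decisions use unrounded
    frequencies.
    """
    thr = thresholds or RoleThresholds()
    ranks = ranks or {}

    # fraction of unit plots where the (layer-combined) cover reaches the
    # dominance threshold
    dom_freq = pd.DataFrame(0.0, index=syn.species, columns=syn.units)
    by_unit: dict[str, list[str]] = {}
    for plot_id, unit in labels.items():
        by_unit.setdefault(unit, []).append(plot_id)
    for unit, plot_ids in by_unit.items():
        counts: dict[str, int] = {}
        for pid in plot_ids:
            for taxon, cover in table[pid].species_covers().items():
                if cover * 100.0 >= thr.dominance_cover:
                    counts[taxon] = counts.get(taxon, 0) + 1
        for taxon, cnt in counts.items():
            dom_freq.at[taxon, unit] = 100.0 * cnt / len(plot_ids)

    roles = pd.DataFrame(index=syn.species, columns=syn.units, dtype=object)
    for unit in syn.units:
        phi_min = thr.phi_for_rank(ranks.get(unit, "association"))
        for sp in syn.species:
            flags = set()
            ph = syn.phi.at[sp, unit]
            pv = syn.fisher_p.at[sp, unit]
            if ph >= phi_min and pv < thr.p_max:
                if name_key(sp) in thr.class_species:
                    flags.add("diagnostic")
                else:
                    flags.add("differential")
            if syn.frequency.at[sp, unit] >= thr.constancy_min:
                flags.add("constant")
            if dom_freq.at[sp, unit] >= thr.dominance_freq:
                flags.add("dominant")
            roles.at[sp, unit] = frozenset(flags)
    return SynopticTable(
        frequency=syn.frequency,
        phi=syn.phi,
        fisher_p=syn.fisher_p,
        n_plots=syn.n_plots,
        roles=roles,
    )
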