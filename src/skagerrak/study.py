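"""Model/Results objects orchestrating the two analysis arms.

:class:`PopGenStudy` wraps a genotype cohort and, on :meth:`~PopGenStudy.fit`,
runs the full population-genetic workflow — diversity panel, pooled locus
summary, chord-distance matrix, bootstrap NJ tree, PCoA ordination, pairwise
Weir-Cockerham theta with permutation tests, and the B-Y-corrected test
families — returning a :class:`PopGenResults` that can render a text summary
or write the complete report bundle.

:class:`DriftSimulation` does the same for the larval-transport arm: one or
more scenario "years" of ocean fields share a release schedule; ``run()``
tracks every super-individual and returns a :class:`DriftResults` with the
per-scenario landing summary and coarse-grid cell counts.

All randomness flows from a single root seed split per stage, so stages can
be re-run independently yet match the full pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import dispersal as disp
from . import diversity as dv
from . import structure as st
from .genotypes import GenotypeTable, allele_frequencies, from_dataframe, read_genepop, read_table

__all__ = ["PopGenStudy", "PopGenResults", "DriftSimulation", "DriftResults"]


def _stage_seeds(seed: int | None, names: list[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


class PopGenStudy:
    """Population-structure analysis of a diploid microsatellite cohort.

    Parameters
    ----------
    table : GenotypeTable
        The genotype data (use :meth:`from_genepop`, :meth:`from_csv` or
        :meth:`from_dataframe` to construct from files).
    g : int, optional
        Standard gene-copy number for rarefied allelic richness; default is
        the per-locus minimum across populations.
    alpha : float
        Family-wise level for the B-Y-corrected HWE and LD test families.
    hwe_steps, ld_reps, fst_perms, boot_reps : int
        Monte-Carlo sizes of the HWE test, LD permutation test, theta
        permutation test and locus bootstrap.
    """

    def __init__(
        self,
        table: GenotypeTable,
        g: int | None = None,
        alpha: float = 0.05,
        hwe_steps: int = 100_000,
        ld_reps: int = 10_000,
        fst_perms: int = 10_000,
        boot_reps: int = 2000,
        chord_combine: str = "mean",
    ) -> None:
        table.validate()
        self.table = table
        self.g = g
        self.alpha = alpha
        self.hwe_steps = hwe_steps
        self.ld_reps = ld_reps
        self.fst_perms = fst_perms
        self.boot_reps = boot_reps
        self.chord_combine = chord_combine

    @classmethod
    def from_genepop(cls, path, **kw) -> "PopGenStudy":
        return cls(read_genepop(path), **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "PopGenStudy":
        return cls(read_table(path), **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "PopGenStudy":
        return cls(from_dataframe(df), **kw)

    def fit(self, seed: int | None = None, structure: bool = True) -> "PopGenResults":
        """Run the whole workflow; ``seed`` drives every Monte-Carlo stage."""
        rngs = _stage_seeds(seed, ["hwe", "ld", "fst", "boot"])
        table = self.table
        pops = table.population_order

        diversity = dv.diversity_table(
            table, g=self.g, hwe_steps=self.hwe_steps, alpha=self.alpha, seed=rngs["hwe"]
        )
        locus_summary = dv.locus_summary(table)
        freq = allele_frequencies(table)
        private = dv.private_alleles(freq)

        ld_labels, ld_p = [], []
        for pop in pops:
            mask = table.pop_mask(pop)
            for i, j in combinations(range(table.n_loci), 2):
                p = dv.ld_permutation_test(
                    table.calls[mask, i, :],
                    table.calls[mask, j, :],
                    reps=self.ld_reps,
                    seed=rngs["ld"],
                )
                ld_labels.append(f"{pop}:{table.loci[i]}x{table.loci[j]}")
                ld_p.append(p)
        ld_family = dv.TestFamilyResult(ld_labels, ld_p, self.alpha)

        chord = tree = ordination = fst = None
        if structure and len(pops) >= 2:
            chord = st.chord_matrix(freq, combine=self.chord_combine)
            if len(pops) >= 3:
                tree = st.bootstrap_nj(
                    table, reps=self.boot_reps, seed=rngs["boot"], combine=self.chord_combine
                )
                ordination = st.pcoa(chord)
            fst = st.fst_matrix(table, reps=self.fst_perms, seed=rngs["fst"])
        elif structure:
            warnings.warn("fewer than 2 populations: structure stages skipped")

        settings = {
            "g": self.g,
            "alpha": self.alpha,
            "hwe_steps": self.hwe_steps,
            "ld_reps": self.ld_reps,
            "fst_perms": self.fst_perms,
            "boot_reps": self.boot_reps,
            "chord_combine": self.chord_combine,
            "seed": seed,
        }
        return PopGenResults(
            model=self,
            diversity=diversity,
            locus_summary=locus_summary,
            private_alleles=private,
            ld_family=ld_family,
            chord=chord,
            tree=tree,
            ordination=ordination,
            fst=fst,
            settings=settings,
        )


@dataclass
class PopGenResults:
    """Fitted population-structure results; see :class:`PopGenStudy`."""

    model: PopGenStudy
    diversity: pd.DataFrame
    locus_summary: pd.DataFrame
    private_alleles: dict[str, int]
    ld_family: dv.TestFamilyResult
    chord: st.DistanceMatrix | None
    tree: st.SupportTree | None
    ordination: st.OrdinationResult | None
    fst: st.FstResult | None
    settings: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Population-structure summary", "=" * 28]
        sizes = self.model.table.population_sizes()
        lines.append(
            f"{len(sizes)} populations, {self.model.table.n_individuals} individuals, "
            f"{self.model.table.n_loci} loci"
        )
        lines.append("")
        lines.append("Pooled locus panel:")
        lines.append(self.locus_summary.round(3).to_string())
        lines.append("")
        lines.append(
            "Private alleles per population: "
            + ", ".join(f"{p}={c}" for p, c in self.private_alleles.items())
        )
        lines.append(
            f"LD family: k={self.ld_family.k}, B-Y adjusted alpha="
            f"{self.ld_family.adjusted_alpha:.5f}, "
            f"{sum(self.ld_family.significant)} significant"
        )
        k_hwe = self.diversity.attrs.get("hwe_family_k")
        a_hwe = self.diversity.attrs.get("hwe_adjusted_alpha")
        lines.append(f"HWE family: k={k_hwe}, B-Y adjusted alpha={a_hwe}")
        if self.fst is not None:
            lines.append("")
            lines.append(
                f"Pairwise theta (lower) / permutation p ({self.fst.permutations} perms, upper):"
            )
            lines.append(self.fst.to_dataframe().round(4).to_string())
        if self.ordination is not None:
            pct = ", ".join(f"{v:.1f}%" for v in self.ordination.percent_variance[:3])
            lines.append(f"PCoA axes 1-3 variance: {pct}")
        if self.tree is not None and self.tree.supports:
            sig = self.tree.significant_splits()
            lines.append(
                f"NJ splits with bootstrap support > {self.tree.support_threshold:.0%}: {len(sig)}"
            )
            for s, v in sorted(sig.items(), key=lambda kv: -kv[1]):
                lines.append(f"  {{{', '.join(sorted(s))}}}  support {v:.2f}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, str]:
        """Write the report bundle (CSV/Newick) and a reproducibility manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, str] = {}

        def w(name: str, writer) -> None:
            path = outdir / name
            writer(path)
            written[name.split(".")[0]] = str(path)

        w("diversity.csv", lambda p: self.diversity.to_csv(p))
        w("locus_summary.csv", lambda p: self.locus_summary.to_csv(p))
        w(
            "private_alleles.csv",
            lambda p: pd.Series(self.private_alleles, name="private_alleles")
            .rename_axis("population")
            .to_csv(p),
        )
        w("ld_tests.csv", lambda p: self.ld_family.to_dataframe().to_csv(p, index=False))
        if self.chord is not None:
            w("chord_distance.csv", lambda p: self.chord.to_dataframe().to_csv(p))
        if self.fst is not None:
            w("fst.csv", lambda p: self.fst.to_dataframe().to_csv(p))
        if self.ordination is not None:
            def _write_ord(p):
                df = self.ordination.to_dataframe()
                df.loc["percent_variance"] = self.ordination.percent_variance
                df.to_csv(p)
            w("pcoa.csv", _write_ord)
        if self.tree is not None:
            w("nj_tree.nwk", lambda p: Path(p).write_text(self.tree.newick() + "\n"))
        manifest = {
            "settings": self.settings,
            "populations": self.model.table.population_sizes(),
            "loci": self.model.table.loci,
            "outputs": sorted(written),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        written["manifest"] = str(outdir / "manifest.json")
        return written

    def plot_pcoa(self, ax=None, axes=(0, 1)):
        """Scatter the populations on two principal coordinates."""
        if self.ordination is None:
            raise ValueError("no ordination available")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        i, j = axes
        C = self.ordination.coordinates
        ax.scatter(C[:, i], C[:, j])
        for lbl, x, y in zip(self.ordination.labels, C[:, i], C[:, j]):
            ax.annotate(lbl, (x, y))
        ax.set_xlabel(f"PCo{i + 1} ({self.ordination.percent_variance[i]:.1f}%)")
        ax.set_ylabel(f"PCo{j + 1} ({self.ordination.percent_variance[j]:.1f}%)")
        return ax


class DriftSimulation:
    """Deterministic multi-scenario larval-drift simulation.

    Parameters
    ----------
    scenarios : mapping
        Scenario name (e.g. a year) -> :class:`~skagerrak.dispersal.OceanFields`.
    release : ReleaseSpec
        Shared release schedule (sites x release days).
    params : SimParams, optional
        Integration step, thresholds, degree-day base, max pelagic duration.
    """

    def __init__(
        self,
        scenarios: Mapping[object, disp.OceanFields],
        release: disp.ReleaseSpec,
        params: disp.SimParams | None = None,
    ) -> None:
        if not scenarios:
            raise ValueError("at least one scenario is required")
        self.scenarios = dict(scenarios)
        self.release = release
        self.params = params or disp.SimParams()

    def run(self) -> "DriftResults":
        frames = [
            disp.run_scenario(fields, self.release, self.params, scenario=name)
            for name, fields in self.scenarios.items()
        ]
        return DriftResults(self, pd.concat(frames, ignore_index=True))


@dataclass
class DriftResults:
    """Per-larva fates for every scenario, with landing aggregation."""

    model: DriftSimulation
    records: pd.DataFrame

    def landing_summary(
        self,
        cell_km: float = 50.0,
        regions: Mapping[str, object] | None = None,
    ) -> disp.LandingSummary:
        any_fields = next(iter(self.model.scenarios.values()))
        return disp.aggregate_landings(
            self.records,
            cell_km=cell_km,
            origin=(any_fields.x0, any_fields.y0),
            regions=regions,
        )

    def status_counts(self) -> pd.DataFrame:
        return (
            self.records.groupby(["scenario", "status"]).size().unstack(fill_value=0)
        )

    def summary(self, regions: Mapping[str, object] | None = None) -> str:
        agg = self.landing_summary(regions=regions)
        lines = ["Larval-drift summary", "=" * 20]
        p = self.model.params
        lines.append(
            f"dt={p.dt:.0f}s, max {p.max_days:.0f} d pelagic, "
            f"{p.dd_threshold:.0f} degree-days (base {p.t_base:.0f} C), "
            f"landing T >= {p.t_threshold:.0f} C, integrator {p.integrator}"
        )
        lines.append("")
        lines.append(agg.summary.round(3).to_string())
        return "\n".join(lines)

    def save(self, outdir: str | Path, regions=None, trajectories: bool = False) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        agg = self.landing_summary(regions=regions)
        written = {}
        agg.summary.to_csv(outdir / "landing_summary.csv")
        written["landing_summary"] = str(outdir / "landing_summary.csv")
        agg.cells.to_csv(outdir / "landing_cells.csv", index=False)
        written["landing_cells"] = str(outdir / "landing_cells.csv")
        if trajectories:
            self.records.to_csv(outdir / "larvae.csv", index=False)
            written["larvae"] = str(outdir / "larvae.csv")
        p = self.model.params
        manifest = {
            "params": {
                "dt": p.dt,
                "max_days": p.max_days,
                "dd_threshold": p.dd_threshold,
                "t_threshold": p.t_threshold,
                "t_base": p.t_base,
                "integrator": p.integrator,
            },
            "scenarios": [str(s) for s in self.model.scenarios],
            "n_released_per_scenario": self.model.release.n_released,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        written["manifest"] = str(outdir / "manifest.json")
        return written
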