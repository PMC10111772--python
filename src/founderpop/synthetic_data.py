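"""Synthetic genotype data with known truth: a forward Wright-Fisher simulator
and a fast unlinked-site drift sampler.

Two generators are provided, both returning :class:`~founderpop.variant_store.GenotypeMatrix`
objects with ground truth attached:

``simulate(cfg)``
    Discrete-generation diploid Wright-Fisher simulation with linkage,
    uniform recombination, Poisson mutation (infinite sites), multiplicative
    fitness (het ``1 - hs``, hom ``1 - s``), explicit sexes and pedigrees,
    population splits, founder events, and admixture pulses.  This is the
    generator for anything where linkage, inbreeding, or selection matters
    (ROH, pedigree F, purging).

``simulate_unlinked(...)``
    Per-site independent drift along a population tree (Balding-Nichols
    branches) with admixture as linear frequency mixing, then binomial
    genotype sampling.  Orders of magnitude faster; used for frequency-based
    statistics (D, f4-ratio, FST calibration) where linkage is irrelevant.

Standing variation is initialized from a draw of the neutral site-frequency
spectrum in linkage equilibrium rather than a long mutation-drift burn-in,
so small scenarios start near equilibrium diversity immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_store import GenotypeMatrix, PopulationSpec

#: default per-bp per-generation mutation rate (large felid estimate)
DEFAULT_MUTATION_RATE = 3.5e-9
#: default generation time in years (metadata only; the simulator is in generations)
DEFAULT_GENERATION_TIME = 5.0


class SimulationFailure(RuntimeError):
    """A population went extinct (or lost one sex) under the configured scenario."""


# ----------------------------------------------------------------- configuration

@dataclass(frozen=True)
class ImpactClass:
    """One deleterious-mutation class with its selection parameters."""

    name: str
    fraction: float      # fraction of new (and standing) mutations in this class
    s: float             # selection coefficient against the derived homozygote
    h: float             # dominance of the derived allele


#: default mutation classes: rare strongly deleterious recessives (stop-gain-like),
#: common mildly deleterious partially recessive (missense-like), and a neutral
#: "synonymous" class used as the load-analysis control.  Fractions are inflated
#: relative to real exome density so toy panels carry countable load sites.
DEFAULT_IMPACT_CLASSES = (
    ImpactClass("HIGH", 0.005, 0.9, 0.05),
    ImpactClass("MODERATE", 0.05, 0.03, 0.2),
    ImpactClass("LOW", 0.05, 0.0, 0.5),
)


@dataclass(frozen=True)
class PopulationConfig:
    """One population in the forward simulation.

    ``sizes`` maps generation -> diploid size from that generation onward; the
    smallest key is the population's first generation.  Root populations
    (``source is None``) exist from generation 0 and may be pre-diverged from
    the shared ancestral frequencies by ``init_F`` (Balding-Nichols).  Split
    populations are created by copying individuals from ``source`` (wild-caught
    founders); ``founder_sexes`` constrains that initial draw to exactly
    (n_males, n_females).
    """

    name: str
    sizes: dict[int, int]
    source: str | None = None
    init_F: float = 0.0
    founder_sexes: tuple[int, int] | None = None

    @property
    def start_generation(self) -> int:
        return min(self.sizes)

    def size_at(self, generation: int) -> int:
        keys = [g for g in self.sizes if g <= generation]
        return self.sizes[max(keys)] if keys else 0


@dataclass(frozen=True)
class Pulse:
    """A one-generation admixture pulse: a fraction of the target's offspring
    draw both parents from the source population."""

    source: str
    target: str
    generation: int
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("pulse fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    populations: tuple[PopulationConfig, ...]
    n_generations: int
    chromosome_lengths: tuple[int, ...] = (10_000_000, 10_000_000)
    mutation_rate: float = DEFAULT_MUTATION_RATE
    recombination_rate: float = 1e-8
    generation_time_years: float = DEFAULT_GENERATION_TIME
    impact_classes: tuple[ImpactClass, ...] = DEFAULT_IMPACT_CLASSES
    init_theta: float = 1e-4          # per-site 4*N*mu targeted by the standing-variation draw
    mating: str = "random"            # "random" or "avoid_sibs" (studbook-like)
    outgroup_name: str = "outgroup"
    outgroup_unknown_fraction: float = 0.02  # outgroup het (unpolarizable) sites
    samples_per_population: int | None = None
    #: populations where selection acts (None = everywhere); lets a scenario
    #: pair a selected population with an otherwise identical neutral control
    selected_in: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if sum(c.fraction for c in self.impact_classes) > 1.0 + 1e-12:
            raise ValueError("impact-class fractions must sum to <= 1")
        if any(min(p.sizes.values()) < 1 for p in self.populations):
            raise ValueError("all population sizes must be >= 1")
        if self.mating not in ("random", "avoid_sibs"):
            raise ValueError("mating must be 'random' or 'avoid_sibs'")

    pulses: tuple[Pulse, ...] = ()


@dataclass
class SimTruth:
    """Ground truth for a simulation: per-site mutation class and selection
    parameters (ancestral allele is always REF by construction), and
    per-individual ancestry fractions and pedigree inbreeding."""

    sites: pd.DataFrame          # chrom, pos, ancestral, category, s, h
    individuals: pd.DataFrame    # sample, population, F_p, ancestry_<pop>...

    def write(self, sites_path, individuals_path) -> None:
        self.sites.to_csv(sites_path, sep="\t", index=False)
        self.individuals.to_csv(individuals_path, sep="\t", index=False)


@dataclass
class SimulationResult:
    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame       # id, sire, dam, sex, generation, population
    truth: SimTruth
    population_spec: PopulationSpec
    config: SimulationConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genotypes.write_vcf(out / "genotypes.vcf")
        self.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
        self.truth.write(out / "truth_sites.tsv", out / "truth_individuals.tsv")
        self.population_spec.to_tsv(out / "populations.tsv")


# ------------------------------------------------------------- neutral spectrum

def neutral_sfs_frequencies(rng: np.random.Generator, n_sites: int,
                            n_copies: int) -> np.ndarray:
    """Derived-allele frequencies drawn from the neutral SFS (P(count=i) ~ 1/i)."""
    i = np.arange(1, n_copies)
    p = (1.0 / i) / np.sum(1.0 / i)
    return rng.choice(i, size=n_sites, p=p) / n_copies


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Drifted daughter frequencies under the Balding-Nichols beta model."""
    if F <= 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    # beta(0, x) degenerates; guard fixed sites
    out = np.where((p <= 0) | (p >= 1), p, rng.beta(np.maximum(a, 1e-12),
                                                    np.maximum(b, 1e-12)))
    return out


# --------------------------------------------------------------- forward WF sim

class _PopState:
    __slots__ = ("haps", "sex", "ids", "ancestry")

    def __init__(self, haps, sex, ids, ancestry):
        self.haps = haps          # (n, 2, S) uint8
        self.sex = sex            # (n,) uint8, 1 = male
        self.ids = ids            # (n,) int
        self.ancestry = ancestry  # (n, n_pops) float


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Run the forward Wright-Fisher simulation described by ``cfg``.

    Deterministic given ``cfg.seed``.  Raises :class:`SimulationFailure` when a
    population goes extinct (or loses one sex) under selection/bottlenecks.
    """
    rng = np.random.default_rng(cfg.seed)
    pops = {p.name: p for p in cfg.populations}
    pop_names = [p.name for p in cfg.populations]
    chrom_names = [f"chr{i + 1}" for i in range(len(cfg.chromosome_lengths))]
    genome_length = float(sum(cfg.chromosome_lengths))

    # --- site catalog (grows with mutation) -------------------------------
    site_chrom: list[np.ndarray] = []
    site_pos: list[np.ndarray] = []
    site_cat: list[np.ndarray] = []

    class_names = [c.name for c in cfg.impact_classes]
    class_s = np.array([c.s for c in cfg.impact_classes] + [0.0])
    class_h = np.array([c.h for c in cfg.impact_classes] + [0.5])
    class_frac = np.array([c.fraction for c in cfg.impact_classes])
    neutral_cat = len(cfg.impact_classes)  # index of the implicit neutral class

    def draw_categories(n):
        u = rng.random(n)
        cats = np.full(n, neutral_cat, dtype=np.int16)
        edges = np.cumsum(class_frac)
        for ci in range(len(class_frac) - 1, -1, -1):
            cats[u < edges[ci]] = ci
        return cats

    # standing variation: Poisson(theta * L * a_n) sites at neutral-SFS freqs
    roots = [p for p in cfg.populations if p.source is None]
    if not roots:
        raise ValueError("at least one root population required")
    n0_copies = 2 * sum(p.size_at(p.start_generation) for p in roots)
    a_n = np.sum(1.0 / np.arange(1, max(n0_copies, 2)))
    n_init = rng.poisson(cfg.init_theta * genome_length * a_n)
    init_chrom = rng.choice(len(cfg.chromosome_lengths), size=n_init,
                            p=np.array(cfg.chromosome_lengths) / genome_length)
    init_pos = np.array([rng.integers(1, cfg.chromosome_lengths[c] + 1)
                         for c in init_chrom], dtype=np.int64)
    site_chrom.append(init_chrom.astype(np.int32))
    site_pos.append(init_pos)
    init_cats = draw_categories(n_init)
    site_cat.append(init_cats)
    p_anc = neutral_sfs_frequencies(rng, n_init, max(n0_copies, 2))
    # selected classes start at the low-frequency edge (young variants near
    # mutation-selection balance), not at neutral-SFS frequencies
    p_anc = np.where(class_s[init_cats] > 0, 1.0 / max(n0_copies, 2), p_anc)

    chrom_arr = np.concatenate(site_chrom)
    pos_arr = np.concatenate(site_pos)
    cat_arr = np.concatenate(site_cat)
    p_init_arr = p_anc.copy()  # standing ancestral frequency; NaN for new mutations

    state: dict[str, _PopState] = {}
    pedigree_rows: list[tuple] = []
    next_id = [1]

    def balanced_sexes(n):
        s = np.zeros(n, dtype=np.uint8)
        s[: n // 2] = 1
        if n % 2:
            s[n // 2] = rng.integers(0, 2)
        return rng.permutation(s)

    def register(pop, generation, n, sires, dams, sexes):
        ids = np.arange(next_id[0], next_id[0] + n)
        next_id[0] += n
        for i in range(n):
            pedigree_rows.append((ids[i], sires[i], dams[i],
                                  "M" if sexes[i] else "F", generation, pop))
        return ids

    # --- initialize root populations --------------------------------------
    for pi, pop in enumerate(cfg.populations):
        if pop.source is not None:
            continue
        n = pop.size_at(pop.start_generation)
        p_pop = _balding_nichols(rng, p_anc, pop.init_F)
        haps = (rng.random((n, 2, len(p_pop))) < p_pop).astype(np.uint8)
        sexes = balanced_sexes(n)
        ids = register(pop.name, 0, n, [0] * n, [0] * n, sexes)
        anc = np.zeros((n, len(pop_names)))
        anc[:, pi] = 1.0
        state[pop.name] = _PopState(haps, sexes, ids, anc)

    def selection_terms():
        """Per-generation cache for viability: (site idx, log(1-hs), safe
        log(1-s), lethal mask)."""
        sel = np.flatnonzero(class_s[cat_arr] > 0)
        if sel.size == 0:
            return None
        s_site = class_s[cat_arr[sel]]
        h_site = class_h[cat_arr[sel]]
        with np.errstate(divide="ignore"):
            log_het = np.log1p(-h_site * s_site)
            log_hom = np.log1p(-s_site)
        lethal = np.isneginf(log_hom)
        return sel, log_het, np.where(lethal, 0.0, log_hom), lethal

    def offspring_fitness(hap0, hap1, terms):
        """Viability of one zygote under multiplicative selection."""
        if terms is None:
            return 1.0
        sel, log_het, log_hom, lethal = terms
        d = hap0[sel].astype(np.int8) + hap1[sel]
        hom = d == 2
        if lethal.any() and bool((hom & lethal).any()):
            return 0.0
        logw = log_het[d == 1].sum() + log_hom[hom].sum()
        return float(np.exp(logw))

    # per-chromosome site index caches, refreshed when catalog changes
    def chrom_index():
        return [np.flatnonzero(chrom_arr == c) for c in range(len(cfg.chromosome_lengths))]

    def make_gamete(haps_ind, cidx):
        g = np.empty(haps_ind.shape[1], dtype=np.uint8)
        for c, idx in enumerate(cidx):
            L = cfg.chromosome_lengths[c]
            start = rng.integers(0, 2)
            k = rng.poisson(cfg.recombination_rate * L)
            if k == 0 or idx.size == 0:
                g[idx] = haps_ind[start, idx]
                continue
            breaks = np.sort(rng.integers(1, L + 1, size=k))
            phase = (start + np.searchsorted(breaks, pos_arr[idx])) % 2
            g[idx] = haps_ind[phase, idx]
        return g

    def parent_table(ped_rows):
        return {r[0]: (r[1], r[2]) for r in ped_rows}

    def choose_pair(pool_state, parents_of):
        males = np.flatnonzero(pool_state.sex == 1)
        females = np.flatnonzero(pool_state.sex == 0)
        if males.size == 0 or females.size == 0:
            raise SimulationFailure("single-sex parent pool")
        for _ in range(20):
            si = males[rng.integers(males.size)]
            di = females[rng.integers(females.size)]
            if cfg.mating == "avoid_sibs":
                ps = parents_of.get(int(pool_state.ids[si]), (0, 0))
                pd_ = parents_of.get(int(pool_state.ids[di]), (0, 0))
                if ps != (0, 0) and ps == pd_:
                    continue
            return si, di
        return si, di  # give up on sib avoidance after 20 tries

    pulses_by_gen: dict[int, list[Pulse]] = {}
    for pulse in cfg.pulses:
        pulses_by_gen.setdefault(pulse.generation, []).append(pulse)

    # --- generation loop ---------------------------------------------------
    for gen in range(1, cfg.n_generations + 1):
        cidx = chrom_index()
        parents_of = parent_table(pedigree_rows)
        new_state: dict[str, _PopState] = {}
        for pi, pop in enumerate(cfg.populations):
            if gen < pop.start_generation:
                continue
            if gen == pop.start_generation and pop.source is not None:
                # split: initial members are wild-caught copies from the source
                src = state[pop.source]
                n = pop.size_at(gen)
                if pop.founder_sexes is not None:
                    n_m, n_f = pop.founder_sexes
                    males = np.flatnonzero(src.sex == 1)
                    females = np.flatnonzero(src.sex == 0)
                    if males.size < n_m or females.size < n_f:
                        raise SimulationFailure(
                            f"{pop.source} cannot supply {n_m}M+{n_f}F founders at "
                            f"generation {gen}")
                    take = np.concatenate([rng.choice(males, n_m, replace=False),
                                           rng.choice(females, n_f, replace=False)])
                else:
                    take = rng.choice(src.haps.shape[0], n, replace=False)
                anc = np.zeros((take.size, len(pop_names)))
                anc[:, pi] = 1.0  # ancestry basis resets at lineage foundation
                new_state[pop.name] = _PopState(src.haps[take].copy(),
                                                src.sex[take].copy(),
                                                src.ids[take].copy(), anc)
                continue
            if pop.name not in state:
                continue
            pool = state[pop.name]
            n_off = pop.size_at(gen)
            selected_here = cfg.selected_in is None or pop.name in cfg.selected_in
            terms = selection_terms() if selected_here else None
            pulse_list = [pl for pl in pulses_by_gen.get(gen, []) if pl.target == pop.name]
            sexes = balanced_sexes(n_off)
            haps = np.empty((n_off, 2, pool.haps.shape[2]), dtype=np.uint8)
            anc = np.empty((n_off, len(pop_names)))
            sires = np.empty(n_off, dtype=int)
            dams = np.empty(n_off, dtype=int)
            attempts = 0
            i = 0
            while i < n_off:
                attempts += 1
                if attempts > 200 * (n_off + 10):
                    raise SimulationFailure(
                        f"population {pop.name} at generation {gen}: mean "
                        f"offspring viability too low (effective extinction)")
                src_state = pool
                for pl in pulse_list:
                    if rng.random() < pl.fraction:
                        src_state = state[pl.source]
                        break
                si, di = choose_pair(src_state, parents_of)
                h0 = make_gamete(src_state.haps[si], cidx)
                h1 = make_gamete(src_state.haps[di], cidx)
                # viability selection: the zygote survives to adulthood w.p. w
                w = offspring_fitness(h0, h1, terms)
                if w < 1.0 and rng.random() >= w:
                    continue
                haps[i, 0], haps[i, 1] = h0, h1
                anc[i] = 0.5 * (src_state.ancestry[si] + src_state.ancestry[di])
                sires[i], dams[i] = src_state.ids[si], src_state.ids[di]
                i += 1
            ids = register(pop.name, gen, n_off, sires, dams, sexes)
            new_state[pop.name] = _PopState(haps, sexes, ids, anc)
        state = new_state

        # --- new mutations (infinite sites) --------------------------------
        total_genomes = sum(st.haps.shape[0] for st in state.values()) * 2
        n_mut = rng.poisson(total_genomes * cfg.mutation_rate * genome_length)
        if n_mut > 0:
            mchrom = rng.choice(len(cfg.chromosome_lengths), size=n_mut,
                                p=np.array(cfg.chromosome_lengths) / genome_length)
            mpos = np.array([rng.integers(1, cfg.chromosome_lengths[c] + 1)
                             for c in mchrom], dtype=np.int64)
            chrom_arr = np.concatenate([chrom_arr, mchrom.astype(np.int32)])
            pos_arr = np.concatenate([pos_arr, mpos])
            cat_arr = np.concatenate([cat_arr, draw_categories(n_mut)])
            p_init_arr = np.concatenate([p_init_arr, np.full(n_mut, np.nan)])
            owners = rng.integers(0, total_genomes, size=n_mut)
            offset = 0
            for st in state.values():
                n_gen = st.haps.shape[0] * 2
                st.haps = np.concatenate(
                    [st.haps, np.zeros((st.haps.shape[0], 2, n_mut), dtype=np.uint8)],
                    axis=2)
                mine = np.flatnonzero((owners >= offset) & (owners < offset + n_gen))
                local = owners[mine] - offset
                st.haps[local // 2, local % 2, st.haps.shape[2] - n_mut + mine] = 1
                offset += n_gen

        # --- prune globally lost sites -------------------------------------
        total = np.zeros(chrom_arr.shape[0], dtype=np.int64)
        for st in state.values():
            total += st.haps.sum(axis=(0, 1)).astype(np.int64)
        keep = total > 0
        if not keep.all():
            chrom_arr, pos_arr, cat_arr = chrom_arr[keep], pos_arr[keep], cat_arr[keep]
            p_init_arr = p_init_arr[keep]
            for st in state.values():
                st.haps = st.haps[:, :, keep]

    # --- assemble output ---------------------------------------------------
    pedigree = pd.DataFrame(pedigree_rows,
                            columns=["id", "sire", "dam", "sex", "generation",
                                     "population"])
    # sort catalog by (chrom, pos); drop duplicate positions (finite-genome collisions)
    order = np.lexsort((pos_arr, chrom_arr))
    chrom_arr, pos_arr, cat_arr = chrom_arr[order], pos_arr[order], cat_arr[order]
    p_init_arr = p_init_arr[order]
    dup = np.concatenate([[False], (np.diff(pos_arr) == 0) & (np.diff(chrom_arr) == 0)])
    sel = ~dup

    sample_names, sample_pop, dosages, sampled_ids = [], [], [], []
    for pop in cfg.populations:
        if pop.name not in state:
            continue
        st = state[pop.name]
        n_take = st.haps.shape[0]
        if cfg.samples_per_population is not None:
            n_take = min(n_take, cfg.samples_per_population)
        for i in range(n_take):
            sample_names.append(f"{pop.name}_{st.ids[i]}")
            sample_pop.append(pop.name)
            dosages.append(st.haps[i].sum(axis=0)[order][sel])
            sampled_ids.append(int(st.ids[i]))

    chrom_arr, pos_arr, cat_arr = chrom_arr[sel], pos_arr[sel], cat_arr[sel]
    p_init_arr = p_init_arr[sel]
    n_sites = chrom_arr.shape[0]
    geno = np.stack(dosages) if dosages else np.zeros((0, n_sites), dtype=np.int8)

    # outgroup: deep-split lineage carrying the ancestral allele; a small
    # fraction of sites is heterozygous there and thus unpolarizable
    og = np.zeros(n_sites, dtype=np.int8)
    og[rng.random(n_sites) < cfg.outgroup_unknown_fraction] = 1
    sample_names.append(f"{cfg.outgroup_name}_1")
    sample_pop.append(cfg.outgroup_name)
    geno = np.vstack([geno, og])

    refalt = np.array(list("ACGT"))[rng.integers(0, 4, size=(n_sites, 2))]
    clash = refalt[:, 0] == refalt[:, 1]
    refalt[clash, 1] = np.array(list("ACGT"))[(rng.integers(1, 4, size=clash.sum())
                                               + np.searchsorted(list("ACGT"),
                                                                 refalt[clash, 0])) % 4]
    n_ind = len(sample_names)
    sites = pd.DataFrame({
        "chrom": [chrom_names[c] for c in chrom_arr],
        "pos": pos_arr,
        "ref": refalt[:, 0],
        "alt": refalt[:, 1],
        "QUAL": np.round(rng.normal(600, 80, n_sites), 2),
        "QD": np.round(np.clip(rng.normal(20, 4, n_sites), 2.5, None), 2),
        "FS": np.round(np.clip(rng.exponential(3, n_sites), 0, 55), 3),
        "MQ": np.round(np.clip(rng.normal(57, 2, n_sites), 41, None), 2),
        "DP": rng.poisson(15 * n_ind, n_sites),
        "MQRankSum": np.round(rng.normal(0, 1, n_sites), 3),
        "ReadPosRankSum": np.round(rng.normal(0, 1, n_sites), 3),
        "ancestral": "unknown",
    })
    gm = GenotypeMatrix(sample_names, sites, geno.astype(np.int8),
                        contig_lengths=dict(zip(chrom_names, cfg.chromosome_lengths)))

    cat_names = class_names + ["NEUTRAL"]
    truth_sites = pd.DataFrame({
        "chrom": sites["chrom"], "pos": sites["pos"], "ancestral": "ref",
        "category": [cat_names[c] for c in cat_arr],
        "s": class_s[cat_arr], "h": class_h[cat_arr],
        "p_init": p_init_arr,
    })
    fp = {iid: pedigree_inbreeding(pedigree, iid) for iid in sampled_ids}
    indiv_rows = []
    for name, pop, iid in zip(sample_names[:-1], sample_pop[:-1], sampled_ids):
        st = state[pop]
        anc = st.ancestry[np.flatnonzero(st.ids == iid)[0]]
        row = {"sample": name, "population": pop, "F_p": fp[iid]}
        row.update({f"ancestry_{p}": anc[k] for k, p in enumerate(pop_names)})
        indiv_rows.append(row)
    og_row = {"sample": sample_names[-1], "population": cfg.outgroup_name, "F_p": 0.0}
    og_row.update({f"ancestry_{p}": 0.0 for p in pop_names})
    indiv_rows.append(og_row)
    truth = SimTruth(truth_sites, pd.DataFrame(indiv_rows))
    spec = PopulationSpec(dict(zip(sample_names, sample_pop)),
                          outgroup=cfg.outgroup_name)
    return SimulationResult(gm, pedigree, truth, spec, cfg)


# ------------------------------------------------------------ pedigree F (Wright)

def pedigree_inbreeding(pedigree: pd.DataFrame, individual: int) -> float:
    """Wright's pedigree inbreeding coefficient F_p by kinship recursion.

    Founders (parent id 0 or absent) are assumed non-inbred and unrelated.
    Raises ``ValueError`` on cyclic pedigrees.
    """
    parents = {int(r.id): (int(r.sire), int(r.dam)) for r in pedigree.itertuples()}
    if individual not in parents:
        raise ValueError(f"individual {individual} not in pedigree")

    depth_memo: dict[int, int] = {}

    def depth(a, trail=()):
        if a == 0 or a not in parents:
            return 0
        if a in trail:
            raise ValueError(f"cyclic pedigree at individual {a}")
        if a not in depth_memo:
            s, d = parents[a]
            depth_memo[a] = 1 + max(depth(s, trail + (a,)), depth(d, trail + (a,)))
        return depth_memo[a]

    kin_memo: dict[tuple[int, int], float] = {}

    def kinship(a, b):
        if a == 0 or b == 0:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in kin_memo:
            return kin_memo[key]
        if a == b:
            s, d = parents.get(a, (0, 0))
            val = 0.5 * (1.0 + kinship(s, d))
        else:
            # recurse through the younger individual's parents
            if depth(a) < depth(b):
                a, b = b, a
            s, d = parents.get(a, (0, 0))
            val = 0.5 * (kinship(s, b) + kinship(d, b))
        kin_memo[key] = val
        return val

    sire, dam = parents[individual]
    depth(individual)  # cycle check on the full ancestry
    return kinship(sire, dam)


# --------------------------------------------------------- unlinked-site sampler

@dataclass(frozen=True)
class DriftPop:
    """A node of the unlinked-site drift model.

    ``F`` is the Balding-Nichols drift from the parent node; ``admixture``
    (donor_name, fraction) mixes the donor node's frequencies into this node's
    parent frequencies before its own drift is applied.  Leaves with
    ``n_samples > 0`` contribute binomially sampled diploid genotypes.
    """

    name: str
    parent: str | None = None
    F: float = 0.05
    n_samples: int = 0
    admixture: tuple[str, float] | None = None


def simulate_unlinked(pops: list[DriftPop], n_sites: int, seed: int,
                      freq_floor: float = 0.01, spacing: int = 100,
                      ) -> tuple[GenotypeMatrix, PopulationSpec, pd.DataFrame]:
    """Simulate unlinked derived-allele frequencies on a population tree.

    Ancestral derived frequencies follow the neutral 1/p density on
    ``[freq_floor, 1 - freq_floor]``; each branch applies Balding-Nichols
    drift; admixture mixes frequencies linearly.  Returns the genotype
    matrix (ancestral allele = REF at every site), a population spec
    (no outgroup designated), and the per-population true frequency table.
    """
    rng = np.random.default_rng(seed)
    lo = freq_floor
    u = rng.random(n_sites)
    p0 = lo * ((1 - lo) / lo) ** u  # inverse-CDF of the 1/p density

    freqs: dict[str, np.ndarray] = {}
    by_name = {p.name: p for p in pops}
    resolved: set[str] = set()

    def resolve(name):
        if name in resolved:
            return
        node = by_name[name]
        if node.parent is None:
            base = p0
        else:
            resolve(node.parent)
            base = freqs[node.parent]
        if node.admixture is not None:
            donor, f = node.admixture
            resolve(donor)
            base = (1 - f) * base + f * freqs[donor]
        freqs[name] = _balding_nichols(rng, base, node.F)
        resolved.add(name)

    for p in pops:
        resolve(p.name)

    names, popmap, rows = [], {}, []
    for p in pops:
        for i in range(p.n_samples):
            names.append(f"{p.name}_{i + 1}")
            popmap[names[-1]] = p.name
    geno = np.vstack([rng.binomial(2, freqs[popmap[s]]) for s in names]) \
        if names else np.zeros((0, n_sites))
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n_sites + 1, dtype=np.int64) * spacing,
        "ref": "A", "alt": "G", "ancestral": "ref",
    })
    gm = GenotypeMatrix(names, sites, geno.astype(np.int8),
                        contig_lengths={"chr1": int((n_sites + 1) * spacing)})
    truth = pd.DataFrame({p.name: freqs[p.name] for p in pops})
    return gm, PopulationSpec(popmap), truth


def simulate_trios(n_families: int, n_sites: int, seed: int,
                   freq_range: tuple[float, float] = (0.05, 0.95),
                   ) -> tuple[GenotypeMatrix, list[tuple[str, str, str]]]:
    """Mendelian father/mother/child trios from a Hardy-Weinberg population.

    Parents are independent HW draws; each child receives one allele per
    parent per site (transmission probability dosage/2).  Returns the matrix
    and the (father, mother, child) sample-name triples.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=n_sites)
    names, rows, trios = [], [], []
    for k in range(n_families):
        father = rng.binomial(2, p)
        mother = rng.binomial(2, p)
        child = rng.binomial(1, father / 2.0) + rng.binomial(1, mother / 2.0)
        for tag, g in (("father", father), ("mother", mother), ("child", child)):
            names.append(f"fam{k + 1}_{tag}")
            rows.append(g)
        trios.append(tuple(names[-3:]))
    sites = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(1, n_sites + 1, dtype=np.int64) * 100,
        "ref": "A", "alt": "G", "ancestral": "ref",
    })
    gm = GenotypeMatrix(names, sites, np.vstack(rows).astype(np.int8),
                        contig_lengths={"chr1": int((n_sites + 1) * 100)})
    return gm, trios


def simulate_hw_cohort(n_individuals: int, n_sites: int, seed: int,
                       freq_range: tuple[float, float] = (0.05, 0.95),
                       ) -> GenotypeMatrix:
    """Independent individuals genotyped at Hardy-Weinberg equilibrium sites."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=n_sites)
    geno = rng.binomial(2, p, size=(n_individuals, n_sites))
    sites = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(1, n_sites + 1, dtype=np.int64) * 100,
        "ref": "A", "alt": "G", "ancestral": "ref",
    })
    return GenotypeMatrix([f"ind_{i + 1}" for i in range(n_individuals)],
                          sites, geno.astype(np.int8),
                          contig_lengths={"chr1": int((n_sites + 1) * 100)})


# ----------------------------------------------------------------------- presets

def founder_captive_config(seed: int = 0, n_wild: int = 40,
                           founder_generation: int = 4, n_generations: int = 16,
                           pulse_fraction: float = 0.0,
                           impact_classes: tuple[ImpactClass, ...] = DEFAULT_IMPACT_CLASSES,
                           init_theta: float = 2e-4,
                           chromosome_lengths: tuple[int, ...] = (8_000_000, 8_000_000),
                           ) -> SimulationConfig:
    """Captive-breeding scenario: a wild source population, two captive
    lineages each founded by a handful of wild-caught animals (2 males and
    4 females in total, split 1M+2F per lineage), growth in captivity, and an
    optional admixture pulse from a diverged donor population into lineage 1."""
    g = founder_generation
    growth = {g: 3, g + 1: 6, g + 2: 10, g + 3: 14, g + 4: 18}
    pops = [
        PopulationConfig("wild", {0: n_wild}),
        PopulationConfig("donor", {0: n_wild // 2}, init_F=0.15),
        PopulationConfig("lineage1", dict(growth), source="wild",
                         founder_sexes=(1, 2)),
        PopulationConfig("lineage2", dict(growth), source="wild",
                         founder_sexes=(1, 2)),
    ]
    pulses = ()
    if pulse_fraction > 0:
        pulses = (Pulse("donor", "lineage1", g + 3, pulse_fraction),)
    return SimulationConfig(
        populations=tuple(pops), pulses=pulses, n_generations=n_generations,
        chromosome_lengths=chromosome_lengths, init_theta=init_theta,
        impact_classes=impact_classes, seed=seed,
        # rescaled mutation rate keeps new variation appearing at toy scale
        mutation_rate=1e-8)


def six_subspecies_config(seed: int = 0, n_per_subspecies: int = 16,
                          n_generations: int = 8,
                          pulse_fraction: float = 0.0,
                          init_theta: float = 1.5e-4) -> SimulationConfig:
    """Six diverged populations (pre-split drift levels differ per lineage,
    one strongly isolated like an island form), with the focal population
    founding two captive lineages from 2 males + 4 females and an optional
    rare admixture pulse from a sister population into lineage 1."""
    drift = {"focal": 0.06, "sister": 0.06, "north": 0.10, "south": 0.08,
             "peninsular": 0.09, "island": 0.22}
    pops = [PopulationConfig(name, {0: n_per_subspecies}, init_F=f)
            for name, f in drift.items()]
    growth = {2: 3, 3: 6, 4: 10, 5: 14}
    pops += [PopulationConfig("lineage1", dict(growth), source="focal",
                              founder_sexes=(1, 2)),
             PopulationConfig("lineage2", dict(growth), source="focal",
                              founder_sexes=(1, 2))]
    pulses = (Pulse("sister", "lineage1", 5, pulse_fraction),) \
        if pulse_fraction > 0 else ()
    return SimulationConfig(populations=tuple(pops), pulses=pulses,
                            n_generations=n_generations,
                            chromosome_lengths=(8_000_000, 8_000_000),
                            init_theta=init_theta, mutation_rate=1e-8,
                            seed=seed)


def neutral_single_population_config(seed: int = 0, n_diploid: int = 50,
                                     theta: float = 0.002,
                                     chromosome_length: int = 50_000,
                                     n_generations: int = 10) -> SimulationConfig:
    """One neutral panmictic population at mutation-drift equilibrium with the
    requested per-site theta = 4*N*mu."""
    mu = theta / (4.0 * n_diploid)
    return SimulationConfig(
        populations=(PopulationConfig("pop", {0: n_diploid}),),
        n_generations=n_generations, chromosome_lengths=(chromosome_length,),
        mutation_rate=mu, init_theta=theta, impact_classes=(), seed=seed)


def purging_pair_config(seed: int = 0, n_generations: int = 20,
                        n_ancestral: int = 60, n_inbred: int = 8,
                        ) -> SimulationConfig:
    """Purging contrast: population X passes through a severe founder event
    and a long small-size phase under selection, while population Y keeps the
    ancestral size with selection switched off (the neutral control of a
    paired design).  HIGH-impact mutations are strongly deleterious and
    nearly recessive (s = 0.9, h = 0.05 — severe loss-of-function variants
    express slightly in heterozygotes, which is what makes their purging
    decisive); LOW-impact sites are neutral controls."""
    classes = (ImpactClass("HIGH", 0.08, 0.9, 0.05),
               ImpactClass("MODERATE", 0.06, 0.05, 0.2),
               ImpactClass("LOW", 0.10, 0.0, 0.5))
    pops = (
        PopulationConfig("ancestral", {0: n_ancestral}),
        PopulationConfig("X", {4: n_inbred, 16: 2 * n_inbred},
                         source="ancestral",
                         founder_sexes=(n_inbred // 2, n_inbred - n_inbred // 2)),
        PopulationConfig("Y", {4: n_ancestral}, source="ancestral"),
    )
    return SimulationConfig(populations=pops, n_generations=n_generations,
                            chromosome_lengths=(6_000_000,) * 3,
                            init_theta=4e-4, impact_classes=classes,
                            mutation_rate=1e-8, selected_in=("X",), seed=seed)
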