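"""Spatially explicit individual-based hybrid-zone simulator.

A one-dimensional column of patches holds three groups — southern parental
speciesA, a central band of (initially empty) hybrid-zone patches, and
northern parental speciesB.  Monoecious diploid individuals carry L unlinked
biallelic loci (a flagged subset diagnostic, initialised as fixed differences
between the parental groups).  Each non-overlapping generation applies, in
order: reproduction within patch (random mating with selfing allowed,
Mendelian transmission, Beverton-Holt-regulated Poisson fecundity), dispersal
(within-group nearest-neighbour moves plus an among-group matrix set by the
current phase), and density regulation truncating each patch to its carrying
capacity K.  No selection and no age structure.

The four-phase scenario design contrasts two divergence histories and three
contact regimes:

* Phase I   — parental groups only; model A (secondary contact) has zero
  among-group migration, model B (speciation with gene flow) keeps low
  speciesA<->speciesB exchange.
* Phase II  — speciesA colonises the middle patches.
* Phase III — once every middle patch reaches 50% of K the scenario's regime
  starts: (i) bidirectional dispersal with both parents, (ii) with speciesB
  only, (iii, model B only) both parents at half rate.
* Phase IV  — all scenarios: bidirectional dispersal between the hybrid zone
  and speciesB only.

Differentiation is summarised by hierarchical F-statistics (F_CT among
groups, F_ST among populations within groups) and hybrid-zone position by the
fitted geographic cline centre of the mean hybrid index per patch.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError, GenotypeMatrix, ValidationError
from .geocline import ModelSpec, TraitClineData, fit_mcmc
from .genocline import hybrid_index

SCENARIOS = ("A.i", "A.ii", "B.i", "B.ii", "B.iii")


@dataclass
class Patch:
    id: int
    group: str
    position_km: float
    K: int


@dataclass
class ScenarioConfig:
    """Phased scenario design; defaults give the reduced desk-scale landscape."""

    model: str = "B"  # A = secondary contact, B = speciation with gene flow
    scenario: str = "ii"  # i / ii / iii (iii only under model B)
    patches_per_group: tuple[int, int, int] = (10, 10, 10)
    K_per_group: tuple[int, int, int] = (50, 25, 50)  # hybrid patches smaller
    extent_km: float = 1000.0
    phase_lengths: tuple[int, int, int, int] = (200, 20, 500, 300)
    n_loci: int = 120
    n_diagnostic: int = 100
    base_migration: float = 0.05  # per-individual among-group emigration prob
    within_migration: float = 0.10  # prob of moving to an adjacent same-group patch
    colonization_rate: float = 0.05  # speciesA -> empty middle patches
    dispersal_scale_km: float = 100.0  # e-folding distance of among-group moves
    # low enough that the parental allele-frequency differential persists
    # through Phase I (divergence WITH gene flow, not homogenisation)
    model_b_phase1_migration: float = 0.002
    trigger_fraction: float = 0.5
    growth_rate: float = 2.0
    n_replicates: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.model not in ("A", "B"):
            raise ConfigurationError("model must be 'A' or 'B'")
        if self.scenario not in ("i", "ii", "iii"):
            raise ConfigurationError("scenario must be 'i', 'ii' or 'iii'")
        if self.scenario == "iii" and self.model != "B":
            raise ConfigurationError("scenario iii is only defined under model B")
        if self.n_diagnostic > self.n_loci:
            raise ConfigurationError("n_diagnostic cannot exceed n_loci")
        if not (0 < self.trigger_fraction <= 1):
            raise ConfigurationError("trigger fraction must be in (0, 1]")

    @property
    def name(self) -> str:
        return f"{self.model}.{self.scenario}"

    @property
    def total_generations(self) -> int:
        return sum(self.phase_lengths)


@dataclass
class SimSnapshot:
    generation: int
    genotypes: GenotypeMatrix
    pops: pd.DataFrame  # pop_id, group, position_km, n
    fst: float = np.nan
    fct: float = np.nan


@dataclass
class SimResult:
    config: ScenarioConfig
    snapshots: list[SimSnapshot]
    fstats: pd.DataFrame  # generation, fst, fct, census per group
    phase_switch_gen: int | None
    extinct: bool = False


def _build_patches(cfg: ScenarioConfig) -> list[Patch]:
    nA, nH, nB = cfg.patches_per_group
    KA, KH, KB = cfg.K_per_group
    n = nA + nH + nB
    pos = np.linspace(0.0, cfg.extent_km, n)
    groups = ["speciesA"] * nA + ["hybrid"] * nH + ["speciesB"] * nB
    Ks = [KA] * nA + [KH] * nH + [KB] * nB
    return [Patch(i, groups[i], float(pos[i]), Ks[i]) for i in range(n)]


def _init_population(cfg: ScenarioConfig, patches: list[Patch], rng) -> list[np.ndarray]:
    """Founding haplotypes: diagnostic loci fixed A=0 / B=1, neutral shared."""
    L = cfg.n_loci
    p_neutral = rng.uniform(0.2, 0.8, size=L - cfg.n_diagnostic)
    state = []
    for patch in patches:
        if patch.group == "hybrid":
            state.append(np.zeros((0, 2, L), dtype=np.int8))
            continue
        n = patch.K
        hap = np.zeros((n, 2, L), dtype=np.int8)
        if patch.group == "speciesB":
            hap[:, :, : cfg.n_diagnostic] = 1
        hap[:, :, cfg.n_diagnostic :] = (
            rng.random((n, 2, L - cfg.n_diagnostic)) < p_neutral
        ).astype(np.int8)
        state.append(hap)
    return state


def _dispersal_matrix(cfg: ScenarioConfig, patches: list[Patch], regime: str) -> np.ndarray:
    """Per-source-patch destination probabilities (n_patches x n_patches)."""
    n = len(patches)
    groups = [p.group for p in patches]
    idx_by_group = {g: [i for i in range(n) if groups[i] == g] for g in set(groups)}
    flows: dict[tuple[str, str], float] = {}
    if regime == "phase1":
        if cfg.model == "B":
            m = cfg.model_b_phase1_migration
            flows = {("speciesA", "speciesB"): m, ("speciesB", "speciesA"): m}
    elif regime == "colonize":
        flows = {("speciesA", "hybrid"): cfg.colonization_rate}
    elif regime == "contact":
        m = cfg.base_migration * (0.5 if cfg.scenario == "iii" else 1.0)
        if cfg.scenario in ("i", "iii"):
            flows = {
                ("speciesA", "hybrid"): m,
                ("hybrid", "speciesA"): m,
                ("speciesB", "hybrid"): m,
                ("hybrid", "speciesB"): m,
            }
        else:  # ii: hybrid zone exchanges only with speciesB
            flows = {("speciesB", "hybrid"): m, ("hybrid", "speciesB"): m}
    elif regime == "phase4":
        m = cfg.base_migration
        flows = {("speciesB", "hybrid"): m, ("hybrid", "speciesB"): m}
    else:
        raise ConfigurationError(f"unknown regime {regime!r}")
    P = np.zeros((n, n))
    for i, patch in enumerate(patches):
        out = 0.0
        # nearest-neighbour moves within the group band
        same = idx_by_group[patch.group]
        pos_in_band = same.index(i)
        for nb in (pos_in_band - 1, pos_in_band + 1):
            if 0 <= nb < len(same):
                P[i, same[nb]] += cfg.within_migration / 2.0
                out += cfg.within_migration / 2.0
        for (src, dst), m in flows.items():
            if patch.group == src:
                targets = idx_by_group.get(dst, [])
                if targets:
                    # migrants settle preferentially in near patches of the
                    # target band (exponential distance decay), then spread by
                    # within-band moves -- this is what shapes the cline
                    d = np.array([abs(patches[t].position_km - patch.position_km) for t in targets])
                    wgt = np.exp(-d / cfg.dispersal_scale_km)
                    wgt /= wgt.sum()
                    for t, wv in zip(targets, wgt):
                        P[i, t] += m * wv
                    out += m
        if out > 1.0:
            raise ConfigurationError("total emigration probability exceeds 1")
        P[i, i] = 1.0 - out
    return P


def run_scenario(
    cfg: ScenarioConfig,
    seed: int | None = None,
    snapshot_gens: tuple[int, ...] = (),
    fstat_every: int = 50,
) -> SimResult:
    """Run one replicate of the phased scenario; see the module docstring."""
    cfg.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 31])
    )
    patches = _build_patches(cfg)
    state = _init_population(cfg, patches, rng)
    n_patch = len(patches)
    hybrid_idx = [i for i, p in enumerate(patches) if p.group == "hybrid"]
    I, II, III, IV = cfg.phase_lengths
    switched = None
    matrices = {r: _dispersal_matrix(cfg, patches, r) for r in ("phase1", "colonize", "contact", "phase4")}
    snapshots: list[SimSnapshot] = []
    fs_rows = []
    snapshot_set = set(snapshot_gens)
    extinct = False
    total = cfg.total_generations
    for gen in range(1, total + 1):
        if gen <= I:
            regime = "phase1"
        elif gen <= I + II:
            regime = "colonize"
        elif gen <= I + II + III:
            if switched is None:
                full = all(
                    state[i].shape[0] >= cfg.trigger_fraction * patches[i].K
                    for i in hybrid_idx
                )
                if full:
                    switched = gen
            regime = "contact" if switched is not None else "colonize"
        else:
            regime = "phase4"
        P = matrices[regime]
        # --- reproduction within patch ---
        offspring: list[np.ndarray] = []
        for i, patch in enumerate(patches):
            hap = state[i]
            n = hap.shape[0]
            if n == 0 or patch.K == 0:
                offspring.append(hap[:0])
                continue
            r = cfg.growth_rate
            expected = n * r / (1.0 + (r - 1.0) * n / patch.K)
            n_off = int(rng.poisson(expected))
            if n_off == 0:
                offspring.append(hap[:0])
                continue
            parents = rng.integers(0, n, size=(n_off, 2))
            L = cfg.n_loci
            kids = np.empty((n_off, 2, L), dtype=np.int8)
            for side in range(2):
                ph = hap[parents[:, side]]  # (n_off, 2, L)
                bits = rng.integers(0, 2, size=(n_off, 1, L))
                kids[:, side, :] = np.take_along_axis(ph, bits, axis=1)[:, 0, :]
            offspring.append(kids)
        # --- dispersal (allele-count conserving reshuffle) ---
        moved: list[list[np.ndarray]] = [[] for _ in range(n_patch)]
        for i in range(n_patch):
            kids = offspring[i]
            if kids.shape[0] == 0:
                continue
            dest = rng.choice(n_patch, size=kids.shape[0], p=P[i])
            for d in np.unique(dest):
                moved[d].append(kids[dest == d])
        new_state = []
        for i, patch in enumerate(patches):
            pool = (
                np.concatenate(moved[i], axis=0)
                if moved[i]
                else np.zeros((0, 2, cfg.n_loci), dtype=np.int8)
            )
            # --- density regulation: random truncation to K ---
            if pool.shape[0] > patch.K:
                keep = rng.permutation(pool.shape[0])[: patch.K]
                pool = pool[keep]
            new_state.append(pool)
        state = new_state
        census = {g: 0 for g in ("speciesA", "hybrid", "speciesB")}
        for i, patch in enumerate(patches):
            census[patch.group] += state[i].shape[0]
        if census["speciesA"] == 0 or census["speciesB"] == 0:
            warnings.warn(f"group extinction at generation {gen}; run terminated")
            extinct = True
        if gen % fstat_every == 0 or gen == total or extinct or gen in snapshot_set:
            gm, pop_tab = _as_genotypes(cfg, patches, state)
            row = {"generation": gen, **{f"census_{g}": v for g, v in census.items()}}
            if gen % fstat_every == 0 or gen == total or extinct:
                fst, fct = hierarchical_fstats(gm, pop_tab.set_index("pop_id")["group"])
                row["fst"], row["fct"] = fst, fct
                fs_rows.append(row)
            if gen in snapshot_set or (extinct or gen == total):
                snapshots.append(
                    SimSnapshot(gen, gm, pop_tab, row.get("fst", np.nan), row.get("fct", np.nan))
                )
        if extinct:
            break
    return SimResult(cfg, snapshots, pd.DataFrame(fs_rows), switched, extinct)


def _as_genotypes(cfg, patches, state) -> tuple[GenotypeMatrix, pd.DataFrame]:
    haps = [h for h in state if h.shape[0] > 0]
    hap = (
        np.concatenate(haps, axis=0)
        if haps
        else np.zeros((0, 2, cfg.n_loci), dtype=np.int8)
    )
    pops = []
    rows = []
    inds = []
    k = 0
    for i, patch in enumerate(patches):
        n = state[i].shape[0]
        if n == 0:
            continue
        pid = f"patch{patch.id:02d}"
        pops.extend([pid] * n)
        inds.extend([f"{pid}_i{j}" for j in range(n)])
        rows.append(
            {
                "pop_id": pid,
                "group": patch.group,
                "position_km": patch.position_km,
                "distance_km": patch.position_km,
                "n": n,
                "K": patch.K,
            }
        )
        k += n
    gm = GenotypeMatrix(
        hap.sum(axis=1),
        inds,
        [f"locus{j}" for j in range(cfg.n_loci)],
        np.array(pops, dtype=object),
        hap,
    )
    return gm, pd.DataFrame(rows)


# ------------------------------------------------------------- F-statistics
def hierarchical_fstats(g: GenotypeMatrix, pop_groups: pd.Series) -> tuple[float, float]:
    """Three-level variance components of allele frequencies.

    Allele copies are partitioned among groups / among populations within
    groups / within populations by unbalanced nested ANOVA per locus;
    components are summed across loci.  Returns (F_ST, F_CT) where F_ST is
    the among-population-within-group share sigma_p / (sigma_p + sigma_w) and
    F_CT the among-group share sigma_g / (sigma_g + sigma_p + sigma_w).
    Monomorphic data yield (nan, nan).
    """
    pops_of = pd.Series(g.pops)
    pop_ids = pd.unique(g.pops)
    groups_of = {p: pop_groups[p] for p in pop_ids}
    group_ids = sorted(set(groups_of.values()))
    if len(group_ids) < 2:
        raise ValidationError("need at least 2 groups")
    # per-pop allele counts per locus
    counts = []
    sizes = []
    for p in pop_ids:
        mask = g.pops == p
        geno = g.genotypes[mask]
        called = geno >= 0
        counts.append(np.where(called, geno, 0).sum(axis=0).astype(float))
        sizes.append(2.0 * called.sum(axis=0))
    counts = np.array(counts)  # (P, L)
    sizes = np.array(sizes)
    grp_index = np.array([group_ids.index(groups_of[p]) for p in pop_ids])
    G = len(group_ids)
    P_, L = counts.shape
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / sizes
    Ng = np.zeros((G, L))
    cg = np.zeros((G, L))
    for gi in range(G):
        sel = grp_index == gi
        Ng[gi] = sizes[sel].sum(axis=0)
        cg[gi] = counts[sel].sum(axis=0)
    N = sizes.sum(axis=0)
    pg = cg / np.maximum(Ng, 1e-12)
    pbar = counts.sum(axis=0) / np.maximum(N, 1e-12)
    ss_w = np.nansum(sizes * freq * (1 - freq), axis=0)
    ss_p = np.nansum(sizes * (freq - pg[grp_index]) ** 2, axis=0)
    ss_g = np.nansum(Ng * (pg - pbar) ** 2, axis=0)
    df_w = N - P_
    df_p = P_ - G
    df_g = G - 1
    ms_w = ss_w / np.maximum(df_w, 1)
    ms_p = ss_p / max(df_p, 1)
    ms_g = ss_g / max(df_g, 1)
    sum_np2_over_Ng = np.zeros(L)
    for gi in range(G):
        sel = grp_index == gi
        sum_np2_over_Ng += (sizes[sel] ** 2).sum(axis=0) / np.maximum(Ng[gi], 1e-12)
    sum_np2_over_N = (sizes**2).sum(axis=0) / np.maximum(N, 1e-12)
    sum_Ng2_over_N = (Ng**2).sum(axis=0) / np.maximum(N, 1e-12)
    n_prime = (N - sum_np2_over_Ng) / max(df_p, 1)
    n_dprime = (sum_np2_over_Ng - sum_np2_over_N) / df_g
    n_tprime = (N - sum_Ng2_over_N) / df_g
    sw = ms_w
    sp = (ms_p - ms_w) / np.maximum(n_prime, 1e-12)
    sg = (ms_g - ms_w - n_dprime * sp) / np.maximum(n_tprime, 1e-12)
    SW, SP, SG = np.nansum(sw), np.nansum(sp), np.nansum(sg)
    tot = SG + SP + SW
    if tot <= 0:
        return np.nan, np.nan
    fst = SP / (SP + SW) if (SP + SW) > 0 else np.nan
    fct = SG / tot
    return float(fst), float(fct)


# ------------------------------------------------------------ cline tracking
def snapshot_schedule(start: int = 500, end: int = 1020) -> tuple[int, ...]:
    """Generations at which the cline centre is tracked: every 5 generations
    for the first 20, then every 50."""
    fine = tuple(range(start, min(start + 21, end + 1), 5))
    coarse = tuple(range(start + 70, end + 1, 50))
    return tuple(sorted(set(fine + coarse)))


def track_cline_centre(
    result: SimResult,
    schedule: tuple[int, ...] | None = None,
    chain_len: int = 4000,
    burnin: int = 1000,
    n_chains: int = 2,
    seed: int = 0,
    min_sd: float = 0.02,
) -> pd.DataFrame:
    """Fitted hybrid-index cline centre at each scheduled generation.

    The per-individual hybrid index is computed from the diagnostic loci
    (parental reference frequencies 0 and 1), averaged per patch, and fitted
    with the fixed-0/1, mirror-tailed cline model under a Gaussian
    population-mean likelihood.  Non-convergent fits are recorded with
    ``centre`` = NaN.
    """
    cfg = result.config
    if schedule is None:
        schedule = tuple(s.generation for s in result.snapshots)
    by_gen = {s.generation: s for s in result.snapshots}
    missing = [t for t in schedule if t not in by_gen]
    if missing:
        raise ValidationError(f"no snapshots at generations {missing}")
    diag = [f"locus{j}" for j in range(cfg.n_diagnostic)]
    spec = ModelSpec("trait", "mirror", "fixed01")
    rows = []
    for t in schedule:
        snap = by_gen[t]
        # reference frequencies from the current parental groups (as a
        # supervised Q-score would use); drift-eroded loci are dropped
        grp = snap.pops.set_index("pop_id")["group"]
        groups = np.array([grp[p] for p in snap.genotypes.pops], dtype=object)
        sub = snap.genotypes.subset(locus_ids=diag)
        pA = sub.genotypes[groups == "speciesA"].mean(axis=0) / 2.0
        pB = sub.genotypes[groups == "speciesB"].mean(axis=0) / 2.0
        keep = np.abs(pA - pB) > 0.2
        if not keep.any():
            raise ValidationError(f"no informative diagnostic loci at generation {t}")
        use = [l for l, k in zip(diag, keep) if k]
        hi = hybrid_index(snap.genotypes, pA[keep], pB[keep], loci=use)
        merged = hi.groupby("pop_id").agg(mean=("h", "mean"), sd=("h", "std"), n=("h", "size"))
        merged = merged.join(snap.pops.set_index("pop_id")["position_km"])
        merged = merged[merged["n"] >= 2]
        data = TraitClineData(
            merged["position_km"].to_numpy(),
            merged["mean"].to_numpy(),
            np.maximum(merged["sd"].fillna(min_sd).to_numpy(), min_sd),
            merged["n"].to_numpy(),
        )
        try:
            fit = fit_mcmc(
                spec,
                data,
                chain_len=chain_len,
                burnin=burnin,
                n_chains=n_chains,
                seed=seed + t,
                interval_params=("centre",),
                profile_points=15,
            )
            iv = fit.intervals["centre"]
            rows.append(
                {
                    "generation": t,
                    "centre": fit.model.centre if fit.converged else np.nan,
                    "centre_raw": fit.model.centre,
                    "low": iv.low,
                    "high": iv.high,
                    "converged": fit.converged,
                }
            )
        except ValidationError:
            rows.append(
                {
                    "generation": t,
                    "centre": np.nan,
                    "centre_raw": np.nan,
                    "low": np.nan,
                    "high": np.nan,
                    "converged": False,
                }
            )
    return pd.DataFrame(rows)


def relative_shift(centre_t: float, centre_ref: float, landscape_extent: float) -> float:
    """Signed percentage change in cline centre relative to landscape extent."""
    if landscape_extent <= 0:
        raise ValidationError("landscape extent must be > 0")
    return 100.0 * (centre_t - centre_ref) / landscape_extent


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Build a ScenarioConfig from a scenario id like 'B.ii'."""
    if name not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {name!r}; valid: {SCENARIOS}")
    model, scenario = name.split(".")
    return ScenarioConfig(model=model, scenario=scenario, **overrides)
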