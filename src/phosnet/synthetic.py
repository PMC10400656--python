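"""Ground-truth networks and simulated phosphoproteomics time courses.

The generator emulates the structure of a two-condition label-free
phosphoproteomics screen: 2 conditions x 11 time points (6-min spacing)
x 4 replicates by default, with multiplicative (log-normal) replicate
noise, per-sample calibration offsets, detection-limit censoring (MNAR)
and random dropouts (MCAR).

Dynamics are generated at the observation granularity.  Each regulator
site follows a piecewise-constant log2 trajectory with sparse two-fold
jumps — large enough for the 25% delta-event rule to see every jump, and
sparse enough that an anti-directional (dephosphorylation) target still
co-stabilizes with its regulator for most transitions.  A target copies
its parent's trajectory at the edge's time lapse (0 or 1), mirrored for
dephosphorylation edges.  Regulator trajectories are resampled until all
pairwise delta-pattern concordances stay at or below a separation bound,
so no regulator looks like a parent of another by construction.

The condition effect is a per-site +/- shift (in log2 units) applied to
the second condition with balanced random signs, so per-sample
calibration cannot absorb it and every simulated site carries a genuine
condition signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ingest import SITE_INDEX, PhosphoTable
from .netinfer import DEPHOS, PHOS, concordance
from .regulators import KINASE, PHOSPHATASE, RegulatorList, regulator_list_from_records


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation settings.

    noise_sd is the log2-scale SD of the per-measurement replicate
    noise; half of it is reused as the SD of per-sample calibration
    offsets (run-to-run intensity drift that normalization must remove),
    so noise_sd = 0 yields bit-identical replicates.  detection_limit is
    a raw-intensity floor below which values are censored to 0 (MNAR);
    mcar_rate is the probability of an independent random dropout.
    effect_size is the per-site |log2| condition shift (balanced random
    signs across sites, so sample-level calibration cannot absorb it).

    Trajectory geometry: regulators toggle between two activity states
    ``jump_size`` log2 units apart (default 4-fold) at ``n_jumps``
    transitions (default ~30% of transitions), and every site sits at a
    per-site baseline ``baseline_lo``..``baseline_hi`` log2 units above
    or below the experiment median.  These ranges keep the relative
    delta-change rule responsive on the median-centered scale: jumps
    stay above 25% of the local magnitude while flat stretches stay far
    enough from the median that replicate noise rarely fakes an event.
    """

    n_conditions: int = 2
    n_times: int = 11
    time_step_min: float = 6.0
    n_replicates: int = 4
    noise_sd: float = 0.25
    detection_limit: float = 0.0
    mcar_rate: float = 0.0
    effect_size: float = 0.5
    base_log2: float = 23.0
    jump_size: float = 2.7
    n_jumps: int | None = None
    baseline_lo: float = 5.0
    baseline_hi: float = 5.4
    max_regulator_concordance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_conditions, self.n_times, self.n_replicates) < 1:
            raise ValueError("design counts must be >= 1")
        if not 0 <= self.mcar_rate <= 1:
            raise ValueError("mcar_rate must lie in [0, 1]")
        if self.noise_sd < 0 or self.detection_limit < 0:
            raise ValueError("noise_sd and detection_limit must be non-negative")

    @property
    def conditions(self) -> list[str]:
        if self.n_conditions == 2:
            return ["control", "cold"]
        return [f"cond{i + 1}" for i in range(self.n_conditions)]

    @property
    def times(self) -> list[float]:
        return [i * self.time_step_min for i in range(self.n_times)]


@dataclass
class GroundTruthNetwork:
    """Regulator sites with roles, target sites, and signed lapsed edges."""

    regulators: list  # (site_key, role)
    targets: list  # site_key
    edges: list  # (regulator_site, target_site, sign in {+1,-1}, lapse in {0,1})

    @property
    def regulator_sites(self) -> list:
        return [s for s, _ in self.regulators]

    @property
    def sites(self) -> list:
        return self.regulator_sites + list(self.targets)

    def regulator_list(self) -> RegulatorList:
        return regulator_list_from_records(
            [(site[0], role, "user") for site, role in self.regulators]
        )

    def edge_set(self) -> set:
        return {(r, t) for r, t, _, _ in self.edges}


def _site_key(protein: str) -> tuple:
    return (protein, 101, "S", 1)


def simulate_network(
    n_regulators: int, n_targets: int, seed: int, two_parent_fraction: float = 0.0
) -> GroundTruthNetwork:
    """Sample a ground-truth signed regulator->target network.

    Each regulator is a kinase or phosphatase (alternating); kinases emit
    phosphorylation (+1) edges and phosphatases dephosphorylation (-1)
    edges.  Each target draws one parent uniformly (or two distinct
    parents for a ``two_parent_fraction`` of targets) and a lapse in
    {0, 1}.  Deterministic under ``seed``.
    """
    if n_regulators < 1 or n_targets < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    regulators = []
    for i in range(n_regulators):
        role = KINASE if i % 2 == 0 else PHOSPHATASE
        prefix = "KIN" if role == KINASE else "PHT"
        regulators.append((_site_key(f"{prefix}{i + 1:03d}"), role))
    targets = [_site_key(f"TGT{j + 1:03d}") for j in range(n_targets)]
    edges = []
    for tgt in targets:
        k = 2 if (n_regulators >= 2 and rng.random() < two_parent_fraction) else 1
        parents = rng.choice(n_regulators, size=k, replace=False)
        for pi in parents:
            site, role = regulators[int(pi)]
            sign = 1 if role == KINASE else -1
            lapse = int(rng.integers(0, 2))
            edges.append((site, tgt, sign, lapse))
    return GroundTruthNetwork(regulators, targets, edges)


def _n_jumps(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    if cfg.n_jumps is not None:
        return cfg.n_jumps
    k0 = max(1, round(0.3 * (cfg.n_times - 1)))  # 3 of the 10 default transitions
    return int(rng.integers(k0, k0 + 2))


def _sample_jump_pattern(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Ternary jump pattern over the T-1 transitions: jumps at random
    transitions, signs a bounded random walk over 3 activity levels."""
    n_trans = cfg.n_times - 1
    k = min(_n_jumps(rng, cfg), n_trans)
    pos = np.sort(rng.choice(n_trans, size=k, replace=False))
    pattern = np.zeros(n_trans, dtype=np.int8)
    level = 0
    for p in pos:
        choices = [s for s in (1, -1) if abs(level + s) <= 1]
        step = choices[int(rng.integers(len(choices)))] if len(choices) > 1 else choices[0]
        pattern[p] = step
        level += step
    return pattern


def _target_pattern(parent: np.ndarray, sign: int, lapse: int) -> np.ndarray:
    """Delta pattern of a noiseless target driven by ``parent``."""
    if lapse == 0:
        return sign * parent
    return np.concatenate([[0], sign * parent[:-1]])


def _patterns_admissible(patterns: list[np.ndarray], bound: float) -> bool:
    """Every possible truth edge discoverable; no cross-regulator pair
    (nor any mirror/lagged target of another regulator) concordant."""
    for p in patterns:
        # dephos and lagged targets must stay concordant with their parent
        if concordance(p, _target_pattern(p, -1, 0), 0) <= bound:
            return False
        if concordance(p, _target_pattern(p, -1, 1), 1) <= bound:
            return False
        if concordance(p, _target_pattern(p, 1, 1), 1) <= bound:
            return False
    for i, pi in enumerate(patterns):
        for j, pj in enumerate(patterns):
            if i == j:
                continue
            for sign in (1, -1):
                for lam in (0, 1):
                    tgt = _target_pattern(pj, sign, lam)
                    for mu in (0, 1):
                        if concordance(pi, tgt, mu) > bound:
                            return False
    return True


def _regulator_patterns(
    rng: np.random.Generator, n: int, cfg: SimulationConfig
) -> list[np.ndarray]:
    """Jointly sampled jump patterns under the admissibility constraints
    (see :func:`_patterns_admissible`); deterministic under the rng."""
    if n == 1:
        for _ in range(10000):
            cand = [_sample_jump_pattern(rng, cfg)]
            if _patterns_admissible(cand, cfg.max_regulator_concordance):
                return cand
    for _ in range(200000):
        cand = [_sample_jump_pattern(rng, cfg) for _ in range(n)]
        if _patterns_admissible(cand, cfg.max_regulator_concordance):
            return cand
    raise RuntimeError(
        "could not find admissible regulator trajectories; lower the regulator "
        "count or raise the number of time points"
    )


def simulate_timecourse(
    net: GroundTruthNetwork, cfg: SimulationConfig, n_background: int = 150
) -> PhosphoTable:
    """Simulate a raw-intensity :class:`PhosphoTable` driven by ``net``.

    Besides the network sites, ``n_background`` inert sites (flat
    trajectory near the experiment median, no condition effect) are
    added: they anchor the per-condition median where the bulk of an
    experiment's unchanged sites would, and give the statistical stage
    genuine null sites.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_times
    patterns = _regulator_patterns(rng, len(net.regulators), cfg)

    # Dynamics (log2 deviations from each site's own baseline).
    dynamics: dict = {}
    for (site, _role), pattern in zip(net.regulators, patterns):
        dynamics[site] = cfg.jump_size * np.concatenate([[0.0], np.cumsum(pattern)])
    parent_of: dict = {}
    for reg, tgt, sign, lapse in net.edges:
        parent_of.setdefault(tgt, []).append((reg, sign, lapse))
    for tgt in net.targets:
        contributions = []
        for reg, sign, lapse in parent_of.get(tgt, []):
            dyn = dynamics[reg]
            lagged = dyn if lapse == 0 else np.concatenate([[dyn[0]], dyn[:-1]])
            contributions.append(sign * lagged)
        dynamics[tgt] = (
            np.mean(contributions, axis=0) if contributions else np.zeros(T)
        )

    sites = list(net.sites)
    baselines = {}
    for i, site in enumerate(sites):
        mag = rng.uniform(cfg.baseline_lo, cfg.baseline_hi)
        baselines[site] = mag if i % 2 == 0 else -mag
    cond_shift = {}
    signs = rng.permutation(
        np.resize(np.array([1.0, -1.0]), len(sites))
    )  # balanced +/- so sample calibration cannot absorb the shift
    for site, s in zip(sites, signs):
        cond_shift[site] = s * cfg.effect_size

    for b in range(n_background):
        site = _site_key(f"BGD{b + 1:03d}")
        sites.append(site)
        dynamics[site] = np.zeros(T)
        baselines[site] = rng.normal(0.0, 1.5)
        cond_shift[site] = 0.0

    conditions = cfg.conditions
    times = cfg.times
    samples = []
    for cond in conditions:
        for t in times:
            for rep in range(1, cfg.n_replicates + 1):
                samples.append(
                    (f"Intensity {cond}_{int(t):02d}_r{rep}", cond, t, f"r{rep}")
                )
    design = pd.DataFrame(
        [(c, t, r) for _, c, t, r in samples],
        index=[s[0] for s in samples],
        columns=["condition", "time_min", "replicate"],
    )

    sample_offsets = rng.normal(0.0, cfg.noise_sd / 2.0, size=len(samples))
    t_index = {t: i for i, t in enumerate(times)}
    mu = np.empty((len(sites), len(samples)))
    for si, site in enumerate(sites):
        traj = cfg.base_log2 + baselines[site] + dynamics[site]
        for ci, (_name, cond, t, _rep) in enumerate(samples):
            v = traj[t_index[t]]
            if cond != conditions[0]:
                v += cond_shift[site]
            mu[si, ci] = v + sample_offsets[ci]
    if cfg.noise_sd > 0:
        mu += rng.normal(0.0, cfg.noise_sd, size=mu.shape)
    data = 2.0**mu
    if cfg.detection_limit > 0:
        data[data < cfg.detection_limit] = 0.0
    if cfg.mcar_rate > 0:
        drop = rng.random(data.shape) < cfg.mcar_rate
        data[drop] = 0.0

    idx = pd.MultiIndex.from_tuples(sites, names=SITE_INDEX)
    intensities = pd.DataFrame(data, index=idx, columns=design.index)
    return PhosphoTable(intensities, design)


# ---------------------------------------------------------------------------
# MaxQuant-dialect writer

_META_COLUMNS = [
    ("Protein", "protein_id"),
    ("Position", "position"),
    ("Amino acid", "residue"),
]


def write_maxquant_like(table: PhosphoTable, path) -> None:
    """Write a Phospho(STY)-dialect TSV that ``read_phospho_table``
    parses back bit-exactly.

    One row per (protein, position, residue); intensities land in
    ``<sample>___<multiplicity>`` columns.  Multiplicity slices a site
    does not carry are left blank (no record on re-read), measured zeros
    are written as 0.
    """
    mults = sorted(set(table.intensities.index.get_level_values("multiplicity"))) or [1]
    rows: dict = {}
    for key, inten in table.intensities.iterrows():
        prot, pos, res, mult = key
        rk = (prot, pos, res)
        row = rows.setdefault(
            rk,
            {
                "Protein": prot,
                "Position": pos,
                "Amino acid": res,
                "Localization prob": None,
                "Reverse": "",
                "Potential contaminant": "",
            },
        )
        meta = table.meta.loc[key]
        prob = meta["localization_prob"]
        if row["Localization prob"] is None or prob > row["Localization prob"]:
            row["Localization prob"] = prob
        if meta["is_reverse"]:
            row["Reverse"] = "+"
        if meta["is_contaminant"]:
            row["Potential contaminant"] = "+"
        for sample in table.design.index:
            row[f"{sample}___{mult}"] = repr(float(inten[sample]))
    columns = (
        ["Protein", "Position", "Amino acid", "Localization prob", "Reverse",
         "Potential contaminant"]
        + [f"{s}___{m}" for s in table.design.index for m in mults]
    )
    df = pd.DataFrame(
        [{c: r.get(c, "") for c in columns} for r in rows.values()], columns=columns
    )
    df.to_csv(path, sep="\t", index=False)


def write_design(table: PhosphoTable, path) -> None:
    """Write the sample-design TSV matching :func:`write_maxquant_like`."""
    out = table.design.reset_index(names="sample_column")
    out.to_csv(path, sep="\t", index=False)


def write_truth_edges(net: GroundTruthNetwork, path) -> None:
    df = pd.DataFrame(
        [
            (r[0], r[1], r[2], r[3], t[0], t[1], t[2], t[3],
             PHOS if sign > 0 else DEPHOS, lapse)
            for r, t, sign, lapse in net.edges
        ],
        columns=[
            "reg_protein", "reg_position", "reg_residue", "reg_multiplicity",
            "tgt_protein", "tgt_position", "tgt_residue", "tgt_multiplicity",
            "sign", "lapse",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Recovery metrics


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float
    sign_accuracy: float
    tp: int
    fp: int
    fn: int


def recovery_metrics(inferred: nx.DiGraph, truth: GroundTruthNetwork) -> RecoveryMetrics:
    """Directed-edge precision/recall/f1 plus sign accuracy on matches.

    precision = TP/(TP+FP), recall = TP/(TP+FN), f1 = 2PR/(P+R); every
    0/0 ratio is 0.  Sign accuracy compares the inferred phos/dephos
    label with the ground-truth edge sign over true-positive edges.
    """
    truth_edges = truth.edge_set()
    truth_sign = {(r, t): s for r, t, s, _ in truth.edges}
    inferred_edges = set(inferred.edges())
    tp_edges = inferred_edges & truth_edges
    tp, fp, fn = (
        len(tp_edges),
        len(inferred_edges - truth_edges),
        len(truth_edges - inferred_edges),
    )
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    good = 0
    for e in tp_edges:
        want = PHOS if truth_sign[e] > 0 else DEPHOS
        if inferred.edges[e].get("sign") == want:
            good += 1
    sign_acc = good / tp if tp else 0.0
    return RecoveryMetrics(precision, recall, f1, sign_acc, tp, fp, fn)
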