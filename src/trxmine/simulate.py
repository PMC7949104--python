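"""Synthetic data generation with ground truth for every pipeline stage.

The generator stands in for the metagenomic inputs the real study mined:
protein families evolved along seeded Yule trees with a conserved CXXC
active-site motif, fragmentary (incomplete-ORF) copies, bit-score-like
pairwise similarities (between-family scores strictly below within-family
scores), profile-hit tables, Nernst-shaped glutathione titrations with
densitometric noise, linear-early-phase kinetic traces and log-linear SEC
ladders.  Every emitted record is covered by a truth table so recovery can
be checked against the planted structure.  All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alignment import align_stats
from .errors import DataError
from .family_mining import DomainHit, SequenceRecord
from .phylo_rep import Tree, TreeNode, patristic_sums, select_medoid, write_newick
from .redox_lab import (
    DEFAULT_COUPLE_E0,
    DEFAULT_TEMPERATURE,
    KineticTrace,
    TitrationPoint,
    TitrationSeries,
    nernst_K,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FamilySimConfig:
    """Conditions for the planted-family sequence simulation.

    Defaults describe a desk-scale version of the mined superfamily: a few
    well-separated families, ~80-residue thioredoxin-like proteins with a
    conserved CGYC active site, one fifth of copies fragmentary, and
    within-family bit scores far above between-family ones.
    """

    n_families: int = 3
    leaves_per_family: int = 16
    root_length: int = 80
    subs_per_site: float = 0.15  # expected substitutions/site per unit branch
    motif: str = "CGYC"
    motif_position: int = 30  # 1-based position of the motif's first residue
    conserve_motif: bool = True
    fragment_fraction: float = 0.2
    within_score_floor: float = 40.0
    between_score_cap: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.leaves_per_family < 1:
            raise DataError("need at least one family with at least one leaf")
        if not (0 <= self.fragment_fraction <= 1):
            raise DataError("fragment_fraction must be in [0, 1]")
        if self.between_score_cap >= self.within_score_floor:
            raise DataError("between-family scores must stay below within-family floor")


@dataclass
class TruthTable:
    """Planted ground truth covering every emitted record."""

    family_of: dict[str, str] = field(default_factory=dict)
    has_start: dict[str, bool] = field(default_factory=dict)
    has_stop: dict[str, bool] = field(default_factory=dict)
    trees: dict[str, str] = field(default_factory=dict)  # family -> newick
    medoid_of: dict[str, str] = field(default_factory=dict)  # family -> leaf id

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SimulatedFamilies:
    records: list[SequenceRecord]
    similarities: list[tuple[str, str, float]]
    hits: list[DomainHit]
    truth: TruthTable
    config: FamilySimConfig


# ---------------------------------------------------------------------------
# Trees and sequence evolution


def yule_tree(n_leaves: int, rng: np.random.Generator, birth_rate: float = 1.0) -> Tree:
    """Ultrametric pure-birth tree: each extant lineage splits at rate
    ``birth_rate``; a final exponential stretch separates the last split from
    the present."""
    if n_leaves < 1:
        raise DataError("need at least one leaf")
    root = TreeNode(label="L0")
    tips = [root]
    while len(tips) < n_leaves:
        wait = rng.exponential(1.0 / (birth_rate * len(tips)))
        for tip in tips:
            tip.branch_length += wait
        idx = int(rng.integers(len(tips)))
        parent = tips.pop(idx)
        left = TreeNode()
        right = TreeNode()
        parent.children = [left, right]
        parent.label = None
        tips.extend([left, right])
    final = rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        tip.branch_length += final
    for i, tip in enumerate(tips):
        tip.label = f"L{i}"
    return Tree(root)


def _mutate(seq: list[str], branch_length: float, frozen: set[int],
            rate: float, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    lam = rate * branch_length
    counts = rng.poisson(lam, size=len(seq))
    for site, k in enumerate(counts):
        if site in frozen:
            continue
        for _ in range(int(k)):
            current = out[site]
            choices = [a for a in AMINO_ACIDS if a != current]
            out[site] = choices[int(rng.integers(19))]
    return out


def evolve_family(
    tree: Tree, config: FamilySimConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve a random root sequence (with the motif planted) down the tree;
    returns leaf label -> sequence."""
    root_seq = [AMINO_ACIDS[int(rng.integers(20))] for _ in range(config.root_length)]
    m0 = config.motif_position - 1
    if m0 + len(config.motif) > config.root_length:
        raise DataError("motif does not fit in the root sequence")
    for i, aa in enumerate(config.motif):
        root_seq[m0 + i] = aa
    frozen = set(range(m0, m0 + len(config.motif))) if config.conserve_motif else set()

    sequences: dict[str, str] = {}

    def walk(node: TreeNode, seq: list[str]) -> None:
        seq = _mutate(seq, node.branch_length, frozen, config.subs_per_site, rng)
        if node.is_leaf:
            sequences[node.label] = "".join(seq)
        for child in node.children:
            walk(child, seq)

    walk(tree.root, root_seq)
    return sequences


# ---------------------------------------------------------------------------
# Family dataset


def simulate_family(config: FamilySimConfig) -> SimulatedFamilies:
    """Generate records, similarity triples, hit table and truth table."""
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    records: list[SequenceRecord] = []
    hits: list[DomainHit] = []
    family_seqs: dict[str, dict[str, str]] = {}

    m0 = config.motif_position  # 1-based motif start on the full-length protein

    for fi in range(config.n_families):
        fam = f"F{fi}"
        tree = yule_tree(config.leaves_per_family, rng)
        # relabel tree leaves with family prefix so truth trees match record ids
        for leaf in tree.leaves():
            leaf.label = f"{fam}_{leaf.label}"
        seqs = evolve_family(tree, config, rng)
        family_seqs[fam] = seqs
        truth.trees[fam] = write_newick(tree)
        truth.medoid_of[fam] = select_medoid(patristic_sums(tree)) if (
            config.leaves_per_family > 1
        ) else next(iter(seqs))

        # fragmentation: an exact seeded count, truncating head or tail
        ids = sorted(seqs)
        n_frag = int(round(config.fragment_fraction * len(ids)))
        frag_ids = list(rng.choice(ids, size=n_frag, replace=False)) if n_frag else []
        for sid in ids:
            seq = seqs[sid]
            has_start = has_stop = True
            motif_start: int | None = m0
            if sid in frag_ids:
                cut = max(1, int(round(0.25 * len(seq))))
                if rng.random() < 0.5:
                    seq = seq[cut:]
                    has_start = False
                    motif_start = m0 - cut if m0 - cut >= 1 else None
                else:
                    seq = seq[:-cut]
                    has_stop = False
                    if motif_start + len(config.motif) - 1 > len(seq):
                        motif_start = None
            rec = SequenceRecord(
                id=sid, residues=seq, has_start=has_start, has_stop=has_stop,
                description=f"family={fam}",
            )
            records.append(rec)
            truth.family_of[sid] = fam
            truth.has_start[sid] = has_start
            truth.has_stop[sid] = has_stop

            evalue = 10.0 ** (-rng.uniform(6.0, 30.0))
            as_from = as_to = None
            if motif_start is not None and config.conserve_motif:
                as_from = motif_start
                as_to = motif_start + len(config.motif) - 1
            hits.append(
                DomainHit(
                    seq_id=sid, model="TRX_clan", evalue=evalue,
                    ali_from=1, ali_to=len(seq),
                    active_site_from=as_from, active_site_to=as_to,
                )
            )
            seqs[sid] = seq

    # similarities: alignment-proportional within families, low noise between
    similarities: list[tuple[str, str, float]] = []
    all_ids = [r.id for r in records]
    seq_of = {r.id: r.residues for r in records}
    for i, a in enumerate(all_ids):
        for b in all_ids[i + 1 :]:
            if truth.family_of[a] == truth.family_of[b]:
                ident, _ = align_stats(seq_of[a], seq_of[b])
                frac = ident / min(len(seq_of[a]), len(seq_of[b]))
                score = config.within_score_floor + 60.0 * frac
            else:
                score = rng.uniform(0.5, config.between_score_cap)
            similarities.append((a, b, round(float(score), 3)))

    return SimulatedFamilies(
        records=records, similarities=similarities, hits=hits,
        truth=truth, config=config,
    )


def write_similarity_table(
    similarities: list[tuple[str, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id1\tid2\tbitscore\n")
        for a, b, s in similarities:
            fh.write(f"{a}\t{b}\t{s}\n")


def write_hit_table(hits: list[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tmodel\tevalue\tali_from\tali_to\tas_from\tas_to\n")
        for h in hits:
            as_from = "" if h.active_site_from is None else h.active_site_from
            as_to = "" if h.active_site_to is None else h.active_site_to
            fh.write(
                f"{h.seq_id}\t{h.model}\t{h.evalue:.3e}\t{h.ali_from}\t{h.ali_to}"
                f"\t{as_from}\t{as_to}\n"
            )


def write_completeness_table(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\thas_start\thas_stop\n")
        for r in records:
            fh.write(f"{r.id}\t{int(r.has_start)}\t{int(r.has_stop)}\n")


# ---------------------------------------------------------------------------
# Titrations, kinetics, SEC


def simulate_titration(
    true_E0: float,
    couple_E0: float = DEFAULT_COUPLE_E0,
    temperature: float = DEFAULT_TEMPERATURE,
    ratios: np.ndarray | None = None,
    n_ratios: int = 12,
    span_decades: float = 5.0,
    noise_sd: float = 0.03,
    gssg: float = 1e-5,
    total_intensity: float = 1000.0,
    seed: int = 0,
    protein_id: str = "sim",
) -> TitrationSeries:
    """Generate a glutathione titration with densitometric noise.

    The true midpoint ratio K is obtained by inverting the Nernst relation
    for ``true_E0``; fractions r/(r+K) receive Gaussian noise (sd
    ``noise_sd``) and are converted to band-intensity pairs summing to
    ``total_intensity`` per lane.  The default grid is ``n_ratios``
    log-spaced ratios spanning ``span_decades`` decades centred on the
    midpoint, emulating 1 uM - 200 mM GSH over constant GSSG.
    """
    rng = np.random.default_rng(seed)
    K = nernst_K(true_E0, temperature, couple_E0)
    if ratios is None:
        half = span_decades / 2.0
        ratios = K * np.logspace(-half, half, n_ratios)
    ratios = np.asarray(ratios, dtype=float)
    if ratios.min() > K or ratios.max() < K:
        import warnings

        warnings.warn("ratio grid lies entirely on one plateau", stacklevel=2)
    fractions = ratios / (ratios + K) + rng.normal(0.0, noise_sd, size=len(ratios))
    fractions = np.clip(fractions, 0.0, 1.0)
    points = [
        TitrationPoint(
            gsh=math.sqrt(r * gssg),
            gssg=gssg,
            i_red=f * total_intensity,
            i_ox=(1.0 - f) * total_intensity,
        )
        for r, f in zip(ratios, fractions)
    ]
    return TitrationSeries(
        protein_id=protein_id, points=points,
        temperature=temperature, couple_E0=couple_E0,
    )


def simulate_kinetics(
    v0: float,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    duration: float = 120.0,
    interval: float = 2.0,
    addition_time: float = 30.0,
    saturation_time: float | None = None,
    seed: int = 0,
) -> KineticTrace:
    """Flat baseline, then a linear fluorescence rise with slope ``v0`` after
    enzyme addition (optionally saturating), plus Gaussian noise."""
    if v0 < 0:
        raise DataError("v0 must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + interval / 2, interval)
    values = np.full_like(times, baseline)
    after = times > addition_time
    elapsed = times[after] - addition_time
    if saturation_time is not None:
        elapsed = np.minimum(elapsed, saturation_time)
    values[after] = baseline + v0 * elapsed
    values = values + rng.normal(0.0, noise_sd, size=len(times))
    return KineticTrace(times=times, values=values, addition_time=addition_time)


def simulate_sec(
    true_slope: float,
    true_intercept: float,
    standard_masses: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """SEC standards (volume, mass) from inverting ln(mass) = a + b*Ve, with
    Gaussian noise on the volumes."""
    if len(standard_masses) < 2:
        raise DataError("need at least 2 SEC standards")
    if true_slope == 0:
        raise DataError("SEC slope must be nonzero")
    rng = np.random.default_rng(seed)
    out = []
    for mass in standard_masses:
        ve = (math.log(mass) - true_intercept) / true_slope
        out.append((ve + rng.normal(0.0, noise_sd), mass))
    return out
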