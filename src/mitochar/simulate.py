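"""Synthetic mitogenome and codon-evolution simulator.

Generates fully annotated circular mitogenomes on the published vertebrate
template — exact printed gene sizes, strands, start/stop codon forms
(including the GTG start of COX1 and incomplete T--/TA- stops) — with
region-specific base composition targets, plus gene families diverged under a
codon-substitution process with a controllable dN/dS (omega), so that every
analysis stage is testable without downloading accessions.

PCG sequences are built codon-wise from position-specific base distributions
with stop codons excluded; where genes overlap (ATP8/ATP6, ATP6/COX3,
ND4L/ND4, ND5/ND6) the bases written first are locked and later genes sample
codons conditioned on them, so every protein-coding gene is an intact open
reading frame in its own frame — exactly the situation in the real genome.

All randomness flows through one explicit numpy Generator; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codons import ALL_CODONS, GeneticCode, codons_of, get_code
from .genome_model import (
    FeatureType,
    GeneFeature,
    MitogenomeRecord,
    Strand,
    normalize_feature,
    reverse_complement,
)
from .presets import (
    REFERENCE_FEATURE_ROWS,
    REGION_BASE_COMPOSITION,
    dedupe_names,
    infer_feature_type,
)

BASES = "TCAG"
_COMP = {"T": "A", "C": "G", "A": "T", "G": "C"}


class GenerationError(RuntimeError):
    """Template constraints cannot be satisfied (e.g. incompatible frames)."""


def _probs(region: str) -> dict[str, float]:
    t, c, a, g = REGION_BASE_COMPOSITION[region]
    total = t + c + a + g
    return {"T": t / total, "C": c / total, "A": a / total, "G": g / total}


def _complement_probs(p: dict[str, float]) -> dict[str, float]:
    return {b: p[_COMP[b]] for b in BASES}


@dataclass
class SimulationConfig:
    """Composition targets and template for mitogenome simulation.

    Defaults mirror the published per-region base percentages of the
    reference genome; the template is its printed 38-feature annotation.
    """

    template: list[tuple[str, int, int, str, str, str]] = field(
        default_factory=lambda: list(REFERENCE_FEATURE_ROWS)
    )
    genome_probs: dict[str, float] = field(default_factory=lambda: _probs("Full genome"))
    dloop_probs: dict[str, float] = field(default_factory=lambda: _probs("D-loop"))
    trna_probs: dict[str, float] = field(default_factory=lambda: _probs("tRNAs"))
    rrna_probs: dict[str, float] = field(default_factory=lambda: _probs("rRNAs"))
    codon_pos_probs: tuple[dict[str, float], ...] = field(
        default_factory=lambda: (_probs("PCGs-1st"), _probs("PCGs-2nd"), _probs("PCGs-3rd"))
    )
    table_id: int = 2
    plant_origin_hairpin: bool = True
    origin_stem: int = 5  # bp per arm: a 10-base stem as in the reference O_L
    origin_loop: int = 5

    def features(self) -> list[GeneFeature]:
        names = dedupe_names([row[0] for row in self.template])
        return sorted(
            (
                normalize_feature(
                    nm, s, e,
                    ftype=infer_feature_type(raw),
                    strand_hint=Strand(strand),
                )
                for nm, (raw, s, e, strand, _sc, _ec) in zip(names, self.template)
            ),
            key=lambda f: (f.start, f.end, f.name),
        )

    def pcg_codons(self) -> dict[str, tuple[str, str]]:
        return {
            raw: (sc, ec) for raw, _s, _e, _st, sc, ec in self.template if sc
        }


def _stop_conditioned_codon_weights(
    pos_probs: tuple[dict[str, float], ...], code: GeneticCode
) -> dict[str, float]:
    w = {}
    for codon in ALL_CODONS:
        if code.is_stop(codon):
            continue
        w[codon] = (
            pos_probs[0][codon[0]] * pos_probs[1][codon[1]] * pos_probs[2][codon[2]]
        )
    total = sum(w.values())
    return {c: v / total for c, v in w.items()}


def _sample_codon(
    rng: np.random.Generator,
    weights: dict[str, float],
    locked: dict[int, str],
) -> str:
    if not locked:
        codons = list(weights)
        p = np.array([weights[c] for c in codons])
        return codons[rng.choice(len(codons), p=p / p.sum())]
    codons = [
        c for c in weights if all(c[i] == b for i, b in locked.items())
    ]
    if not codons:
        raise GenerationError(f"no sense codon matches locked pattern {locked}")
    p = np.array([weights[c] for c in codons])
    return codons[rng.choice(len(codons), p=p / p.sum())]


def _sample_bases(rng: np.random.Generator, probs: dict[str, float], n: int) -> list[str]:
    idx = rng.choice(4, size=n, p=np.array([probs[b] for b in BASES]))
    return [BASES[i] for i in idx]


def _pcg_codon_slots(feature: GeneFeature, stop: str) -> tuple[list[list[int]], list[tuple[int, str]]]:
    """Genome positions (1-based) of each codon of a PCG, 5'->3' on the coding
    strand, plus fixed trailing bases for incomplete stops.

    Returns (codon slots, trailing locks as (genome position, coding base)).
    """
    size = feature.size
    tail = size % 3
    n_codons = size // 3
    if feature.strand is Strand.H:
        coding_positions = list(range(feature.start, feature.end + 1))
    else:
        coding_positions = list(range(feature.end, feature.start - 1, -1))
    slots = [coding_positions[3 * i : 3 * i + 3] for i in range(n_codons)]
    trailing = []
    if tail:
        want = "T" if tail == 1 else "TA"
        if stop and stop.replace("-", "") != want:
            raise GenerationError(
                f"{feature.name}: size {size} leaves {tail} trailing bases, "
                f"incompatible with stop {stop!r}"
            )
        for k, base in enumerate(want):
            trailing.append((coding_positions[3 * n_codons + k], base))
    return slots, trailing


def simulate_mitogenome(
    config: SimulationConfig | None = None,
    seed: int | np.random.Generator = 0,
    identifier: str = "simulated",
) -> MitogenomeRecord:
    """Simulate one annotated circular mitogenome on the template.

    Feature coordinates, strands and sizes follow the template exactly; PCGs
    are intact ORFs with the template's start/stop forms; light-strand
    features are inserted as reverse complements; the longest intergenic gap
    receives a planted stem-loop emulating the light-strand replication
    origin.
    """
    cfg = config or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code = get_code(cfg.table_id)
    features = cfg.features()
    length = max(f.end for f in features)
    seq = np.array(["N"] * length, dtype="<U1")
    locked = np.zeros(length, dtype=bool)

    def lock(pos: int, base: str, who: str) -> None:
        i = pos - 1
        if locked[i]:
            if seq[i] != base:
                raise GenerationError(
                    f"{who}: position {pos} needs {base} but is locked to {seq[i]}"
                )
            return
        seq[i] = base
        locked[i] = True

    # background: whole genome, then region-specific fills (H orientation for
    # D-loop/rRNA; L-strand tRNAs get complement-swapped probabilities so the
    # light-strand gene itself has tRNA-like composition)
    seq[:] = _sample_bases(rng, cfg.genome_probs, length)
    for f in features:
        if f.ftype is FeatureType.TRNA:
            p = cfg.trna_probs if f.strand is Strand.H else _complement_probs(cfg.trna_probs)
        elif f.ftype is FeatureType.RRNA:
            p = cfg.rrna_probs
        elif f.ftype is FeatureType.CONTROL:
            p = cfg.dloop_probs
        else:
            continue
        seq[f.start - 1 : f.end] = _sample_bases(rng, p, f.size)

    pcg_codons = cfg.pcg_codons()
    pcgs = [f for f in features if f.ftype is FeatureType.PCG]
    plans = {}
    for f in pcgs:
        start_codon, stop = pcg_codons.get(f.name, ("ATG", "TAA"))
        slots, trailing = _pcg_codon_slots(f, stop)
        plans[f.name] = (f, start_codon, stop, slots, trailing)

    def coding_base(f: GeneFeature, base: str) -> str:
        return base if f.strand is Strand.H else _COMP[base]

    # pass 1: lock every start codon, complete stop codon and incomplete stop
    # tail; conflicts between overlapping genes are detected here
    for f, start_codon, stop, slots, trailing in plans.values():
        for pos, b in zip(slots[0], start_codon):
            lock(pos, coding_base(f, b), f.name)
        if stop in ("TAA", "TAG", "AGA", "AGG"):
            for pos, b in zip(slots[-1], stop):
                lock(pos, coding_base(f, b), f.name)
        for pos, b in trailing:
            lock(pos, coding_base(f, b), f.name)

    # pass 2: fill interior codons, conditioning on anything already locked
    weights = _stop_conditioned_codon_weights(cfg.codon_pos_probs, code)
    for f, _start_codon, stop, slots, _trailing in plans.values():
        interior = slots[1:-1] if stop in ("TAA", "TAG", "AGA", "AGG") else slots[1:]
        for slot in interior:
            constraints = {
                k: coding_base(f, seq[pos - 1])
                for k, pos in enumerate(slot)
                if locked[pos - 1]
            }
            codon = _sample_codon(rng, weights, constraints)
            for pos, b in zip(slot, codon):
                lock(pos, coding_base(f, b), f.name)

    if cfg.plant_origin_hairpin:
        _plant_hairpin(rng, seq, locked, features, cfg)

    return MitogenomeRecord(
        identifier=identifier, sequence="".join(seq), features=features
    )


def _plant_hairpin(rng, seq, locked, features, cfg) -> None:
    """Write an inverted repeat into the longest intergenic gap (the O_L gap
    of the canonical gene order)."""
    best = None
    for up, down in zip(features, features[1:]):
        gap = down.start - up.end - 1
        if best is None or gap > best[0]:
            best = (gap, up.end + 1, down.start - 1)
    gap, lo, hi = best
    span = cfg.origin_stem * 2 + cfg.origin_loop
    if gap < span:
        return
    offset = lo + (gap - span) // 2
    if locked[offset - 1 : offset - 1 + span].any():
        return
    arm = _sample_bases(rng, cfg.genome_probs, cfg.origin_stem)
    loop = _sample_bases(rng, cfg.genome_probs, cfg.origin_loop)
    hairpin = arm + loop + list(reverse_complement("".join(arm)))
    seq[offset - 1 : offset - 1 + span] = hairpin


def expected_base_composition(config: SimulationConfig | None = None) -> dict[str, float]:
    """Expected genome-wide base fractions implied by the configured region
    targets and the template layout (the size-weighted mixture actually
    sampled, with stop-codon exclusion folded into the PCG marginals).

    Overlap double-writes and locked start/stop codons shift the realization
    by well under one percentage point and are ignored here.
    """
    cfg = config or SimulationConfig()
    code = get_code(cfg.table_id)
    features = cfg.features()
    length = max(f.end for f in features)
    weights = _stop_conditioned_codon_weights(cfg.codon_pos_probs, code)
    marginals = [dict.fromkeys(BASES, 0.0) for _ in range(3)]
    for codon, w in weights.items():
        for i, b in enumerate(codon):
            marginals[i][b] += w
    pcg_mean = {b: sum(m[b] for m in marginals) / 3 for b in BASES}

    acc = dict.fromkeys(BASES, 0.0)
    covered = 0
    for f in features:
        if f.ftype is FeatureType.PCG:
            p = pcg_mean if f.strand is Strand.H else _complement_probs(pcg_mean)
        elif f.ftype is FeatureType.TRNA:
            p = cfg.trna_probs if f.strand is Strand.H else _complement_probs(cfg.trna_probs)
        elif f.ftype is FeatureType.RRNA:
            p = cfg.rrna_probs
        else:
            p = cfg.dloop_probs
        for b in BASES:
            acc[b] += f.size * p[b]
        covered += f.size
    gaps = length - min(covered, length)
    # overlapping features over-count 'covered'; approximate the residual
    # unannotated fraction as non-negative
    for b in BASES:
        acc[b] += max(gaps, 0) * cfg.genome_probs[b]
    total = sum(acc.values())
    return {b: acc[b] / total for b in BASES}


# ---------------------------------------------------------------------------
# codon-substitution evolution


def _substitution_rates(
    code: GeneticCode, omega: float, kappa: float
) -> dict[str, list[tuple[str, float]]]:
    """Per-sense-codon single-nucleotide substitution rates: transitions get
    factor kappa, nonsynonymous changes factor omega, mutations to stops
    rate 0 (rejected)."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    rates: dict[str, list[tuple[str, float]]] = {}
    for codon in code.sense_codons:
        targets = []
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                nxt = codon[:pos] + b + codon[pos + 1 :]
                if code.is_stop(nxt):
                    continue
                r = kappa if (codon[pos], b) in transitions else 1.0
                if code.translate(nxt) != code.translate(codon):
                    r *= omega
                targets.append((nxt, r))
        rates[codon] = targets
    return rates


def evolve_family(
    ancestor_cds: str,
    guide_tree: str | dendropy.Tree,
    omega: float,
    kappa: float = 1.0,
    seed: int | np.random.Generator = 0,
    genetic_code: GeneticCode | None = None,
) -> dict[str, str]:
    """Evolve a CDS along a guide tree under a codon substitution process.

    Branch lengths are expected substitutions per codon (rates are normalized
    against the root sequence's codon composition under the configured
    process).  A trailing complete stop codon and incomplete-stop tail bases
    are held fixed; interior codons never pass through stops.  Returns a
    gap-free alignment keyed by leaf taxon label.
    """
    if omega <= 0:
        raise GenerationError("omega must be > 0")
    code = genetic_code or get_code()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = (
        guide_tree
        if isinstance(guide_tree, dendropy.Tree)
        else dendropy.Tree.get(data=guide_tree, schema="newick")
    )
    cds = ancestor_cds.upper()
    codons = codons_of(cds)
    tail = cds[len(codons) * 3 :]
    evolving = list(codons)
    fixed_stop = ""
    if evolving and code.is_stop(evolving[-1]):
        fixed_stop = evolving.pop()
    for i, c in enumerate(evolving):
        if code.is_stop(c):
            raise GenerationError(f"ancestor has internal stop {c} at codon {i + 1}")

    rates = _substitution_rates(code, omega, kappa)
    total_rate = {c: sum(r for _, r in ts) for c, ts in rates.items()}
    mean_rate = sum(total_rate[c] for c in evolving) / len(evolving)
    if mean_rate == 0:
        raise GenerationError("substitution process has zero rate")

    def evolve_branch(state: list[str], t: float) -> list[str]:
        out = list(state)
        for i, codon in enumerate(out):
            # calendar time such that the composition-averaged substitution
            # rate yields t expected substitutions per codon
            remaining = t / mean_rate
            while True:
                r = total_rate[codon]
                if r == 0:
                    break
                wait = rng.exponential(1.0 / r)
                if wait > remaining:
                    break
                remaining -= wait
                targets = rates[codon]
                probs = np.array([w for _, w in targets])
                codon = targets[rng.choice(len(targets), p=probs / probs.sum())][0]
            out[i] = codon
        return out

    states: dict[int, list[str]] = {id(tree.seed_node): evolving}
    result: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = states[id(node)]
        else:
            parent_state = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            state = evolve_branch(parent_state, t) if t > 0 else list(parent_state)
            states[id(node)] = state
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"taxon{len(result) + 1}"
            result[label] = "".join(state) + fixed_stop + tail
    return result


# ---------------------------------------------------------------------------
# clade-structured datasets


@dataclass
class CladeDataset:
    """A set of simulated mitogenomes with known clade membership."""

    records: list[MitogenomeRecord]
    clades: dict[str, int]  # taxon label -> clade index
    guide_tree_newick: str


def clade_guide_tree(
    n_taxa: int, n_clades: int, within: float = 0.02, between: float = 0.25
) -> tuple[str, dict[str, int]]:
    """Newick guide tree with taxa split into clades; between-clade divergence
    exceeds within-clade.  Three clades get the nested shape
    (cladeA,(cladeB,cladeC)); other counts a star of clades; one clade is a
    simple star (no false structure)."""
    if n_taxa < 3:
        raise GenerationError("need at least 3 taxa")
    sizes = [n_taxa // n_clades + (1 if i < n_taxa % n_clades else 0) for i in range(n_clades)]
    labels = [f"taxon{i + 1}" for i in range(n_taxa)]
    clades: dict[str, int] = {}
    groups: list[list[str]] = []
    k = 0
    for ci, size in enumerate(sizes):
        group = labels[k : k + size]
        for lab in group:
            clades[lab] = ci
        groups.append(group)
        k += size

    def star(group: list[str], tip: float) -> str:
        if len(group) == 1:
            return f"{group[0]}:{tip}"
        return "(" + ",".join(f"{lab}:{tip}" for lab in group) + f")"

    if n_clades == 1:
        newick = star(groups[0], within)
        if not newick.startswith("("):
            newick = f"({newick})"
        return newick + ";", clades
    subtrees = [f"{star(g, within)}:{between}" if len(g) > 1 else f"{g[0]}:{between + within}" for g in groups]
    if n_clades == 3:
        newick = f"({subtrees[0]},({subtrees[1]},{subtrees[2]}):{between / 2});"
    else:
        newick = "(" + ",".join(subtrees) + ");"
    return newick, clades


def simulate_clade_dataset(
    n_taxa: int,
    n_clades: int = 3,
    seed: int | np.random.Generator = 0,
    omega: float = 0.1,
    kappa: float = 1.0,
    within: float = 0.02,
    between: float = 0.25,
    config: SimulationConfig | None = None,
) -> CladeDataset:
    """Simulate a family of annotated mitogenomes whose PCGs diverged along a
    clade-structured guide tree under purifying selection (default omega 0.1).

    All taxa share the template annotation; each PCG family is evolved from
    the base genome's CDS and written back into each taxon's sequence (later
    genes overwrite earlier ones across overlaps, so extracted overlap codons
    may disagree between the two frames — as alignment artifacts do in real
    concatenations)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config or SimulationConfig()
    base = simulate_mitogenome(cfg, seed=rng, identifier="ancestor")
    newick, clades = clade_guide_tree(n_taxa, n_clades, within, between)
    labels = list(clades)
    per_taxon_seq = {
        lab: np.array(list(base.sequence), dtype="<U1") for lab in labels
    }
    for f in base.pcgs:
        ancestor = base.feature_sequence(f, coding_strand=True)
        tips = evolve_family(ancestor, newick, omega=omega, kappa=kappa, seed=rng)
        for lab in labels:
            evolved = tips[lab]
            written = (
                evolved if f.strand is Strand.H else reverse_complement(evolved)
            )
            per_taxon_seq[lab][f.start - 1 : f.end] = list(written)
    records = [
        MitogenomeRecord(
            identifier=lab,
            sequence="".join(per_taxon_seq[lab]),
            features=list(base.features),
        )
        for lab in labels
    ]
    return CladeDataset(records=records, clades=clades, guide_tree_newick=newick)


__all__ = [
    "SimulationConfig",
    "GenerationError",
    "simulate_mitogenome",
    "expected_base_composition",
    "evolve_family",
    "clade_guide_tree",
    "simulate_clade_dataset",
    "CladeDataset",
]
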