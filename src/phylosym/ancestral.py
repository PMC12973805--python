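"""Presence/absence coding and asymmetric Wagner parsimony on the host
phylogeny.

Each taxon's presence pattern over host species is mapped onto the host
tree and the minimal-cost history of gains (0 -> 1) and losses (1 -> 0)
is reconstructed by dynamic programming (Sankoff) with asymmetric
penalties, gain costing 1.5 and loss 1 by default, so the
reconstruction prefers a single ancient gain followed by losses over
repeated independent gains.  Polytomies are handled natively by the DP.

Presence coding treats a taxon as absent in a host species only when it
fails both criteria there: mean relative abundance below 1% AND
prevalence across that species' replicate samples below 20% (an OR
variant exists for sensitivity analysis).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio

from .errors import InputError, LabelError, MetadataError
from .tables_io import FeatureTable, SampleMetadata, relative_abundance


@dataclasses.dataclass
class PresenceMatrix:
    data: pd.DataFrame  # taxa x species, entries in {0, 1}
    abundance_threshold: float
    prevalence_threshold: float


@dataclasses.dataclass
class EventMap:
    """Per-branch gain/loss tallies plus the reconstruction itself.

    ``events`` maps (parent_name, child_name) -> {"gains": int,
    "losses": int} aggregated over taxa; ``states`` holds one
    deterministic optimal labeling (taxa x node-name); ``total_cost``
    is labeling-independent.
    """

    events: dict[tuple[str, str], dict[str, int]]
    states: pd.DataFrame
    total_cost: float
    gain_penalty: float
    loss_penalty: float
    per_taxon_events: dict[str, dict[tuple[str, str], str]]

    @property
    def total_gains(self) -> int:
        return sum(e["gains"] for e in self.events.values())

    @property
    def total_losses(self) -> int:
        return sum(e["losses"] for e in self.events.values())


def code_presence(
    table: FeatureTable,
    metadata: SampleMetadata,
    species_key: str = "species",
    abundance_threshold: float = 0.01,
    prevalence_threshold: float = 0.20,
    rule: str = "and",
) -> PresenceMatrix:
    """Binary taxa x species presence matrix.

    With the default ``rule='and'`` a taxon is absent in a species iff
    its mean relative abundance there is below ``abundance_threshold``
    AND its prevalence among that species' samples is below
    ``prevalence_threshold``; ``rule='or'`` marks absence when either
    criterion fails.
    """
    if rule not in ("and", "or"):
        raise InputError(f"unknown rule {rule!r}")
    metadata.require_cover(table)
    species = metadata.factor(species_key, table.sample_ids)
    if species.isna().any():
        raise MetadataError("samples without a species assignment")
    rel = relative_abundance(table)
    cols = {}
    for sp, samples in species.groupby(species).groups.items():
        samples = list(samples)
        if not samples:
            raise MetadataError(f"species {sp!r} has no samples")
        mean_ra = rel.data[samples].mean(axis=1)
        prev = (table.data[samples] > 0).mean(axis=1)
        low_ab = mean_ra < abundance_threshold
        low_prev = prev < prevalence_threshold
        absent = (low_ab & low_prev) if rule == "and" else (low_ab | low_prev)
        cols[str(sp)] = (~absent).astype(int)
    data = pd.DataFrame(cols)
    return PresenceMatrix(data, abundance_threshold, prevalence_threshold)


def _sankoff_one(
    tree: skbio.TreeNode,
    states: Mapping[str, int],
    gain: float,
    loss: float,
) -> tuple[float, dict[str, int], dict[tuple[str, str], str]]:
    """Minimal-cost binary labeling of one character.

    Transition cost on a branch: 0 -> 1 is ``gain``, 1 -> 0 is
    ``loss``, else 0.  A character present at the root is charged one
    gain on a virtual root edge (the family had to originate
    somewhere); without this charge the asymmetric penalty could never
    favor a single subtree gain over root presence plus losses.  Ties
    prefer state 0 at the root and in the traceback, giving one
    deterministic optimal labeling.
    Returns (cost, node states, branch events); a root origin is
    reported as a gain on the branch ("origin", root name).
    """
    inf = float("inf")
    cost: dict[int, list[float]] = {}
    for node in tree.postorder():
        if node.is_tip():
            s = states[node.name]
            cost[id(node)] = [0.0 if s == 0 else inf, 0.0 if s == 1 else inf]
        else:
            c = [0.0, 0.0]
            for child in node.children:
                cc = cost[id(child)]
                c[0] += min(cc[0], gain + cc[1])
                c[1] += min(loss + cc[0], cc[1])
            cost[id(node)] = c
    root_cost = cost[id(tree)]
    total = min(root_cost[0], gain + root_cost[1])
    assignment: dict[str, int] = {}
    events: dict[tuple[str, str], str] = {}
    root_state = 0 if root_cost[0] <= gain + root_cost[1] else 1
    if root_state == 1:
        root_name = tree.name if tree.name is not None else f"node-{id(tree)}"
        events[("origin", root_name)] = "gain"
    stack = [(tree, root_state)]
    while stack:
        node, s = stack.pop()
        name = node.name if node.name is not None else f"node-{id(node)}"
        assignment[name] = s
        for child in getattr(node, "children", []):
            cc = cost[id(child)]
            if s == 0:
                child_state = 0 if cc[0] <= gain + cc[1] else 1
            else:
                child_state = 0 if loss + cc[0] <= cc[1] else 1
            if child_state != s:
                cname = child.name if child.name is not None else f"node-{id(child)}"
                events[(name, cname)] = "gain" if child_state == 1 else "loss"
            stack.append((child, child_state))
    return total, assignment, events


def _name_internal_nodes(tree: skbio.TreeNode) -> skbio.TreeNode:
    tree = tree.copy()
    i = 0
    for node in tree.preorder():
        if not node.is_tip() and not node.name:
            node.name = f"anc{i}"
            i += 1
    return tree


def wagner_parsimony(
    tree: skbio.TreeNode,
    presence: PresenceMatrix,
    gain_penalty: float = 1.5,
    loss_penalty: float = 1.0,
) -> EventMap:
    """Asymmetric Wagner parsimony over every taxon in the presence
    matrix, aggregating gain/loss events per host-tree branch."""
    tree = _name_internal_nodes(tree)
    leaves = {t.name for t in tree.tips()}
    missing = leaves - set(presence.data.columns)
    if missing:
        raise LabelError(f"species missing from presence matrix: {sorted(missing)}")
    all_binary = presence.data[sorted(leaves)].isin([0, 1]).all().all()
    if not all_binary:
        raise InputError("presence matrix must be binary")
    branch_events: dict[tuple[str, str], dict[str, int]] = {
        ("origin", tree.name): {"gains": 0, "losses": 0}
    }
    for node in tree.preorder():
        for child in getattr(node, "children", []):
            branch_events[(node.name, child.name)] = {"gains": 0, "losses": 0}
    total = 0.0
    states_rows = {}
    per_taxon: dict[str, dict[tuple[str, str], str]] = {}
    for taxon, row in presence.data.iterrows():
        tip_states = {sp: int(row[sp]) for sp in leaves}
        cost, assignment, events = _sankoff_one(
            tree, tip_states, gain_penalty, loss_penalty
        )
        total += cost
        states_rows[taxon] = assignment
        per_taxon[taxon] = events
        for branch, kind in events.items():
            branch_events[branch]["gains" if kind == "gain" else "losses"] += 1
    states = pd.DataFrame.from_dict(states_rows, orient="index")
    return EventMap(branch_events, states, float(total), gain_penalty,
                    loss_penalty, per_taxon)


def lineage_shift_report(
    events: EventMap,
    annotations: Mapping[str, str] | None = None,
    keep: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy per-branch listing of gained and lost taxa.

    ``annotations`` maps taxon -> functional label (e.g. putative
    nitrogen fixer); ``keep`` restricts the report to taxa whose label
    is in that set.  Requesting a filter without annotations, or a
    label no taxon carries, is an input error.
    """
    annotations = dict(annotations or {})
    if keep is not None:
        keep_set = set(keep)
        known = set(annotations.values())
        unknown = keep_set - known
        if unknown:
            raise InputError(f"unknown annotation labels: {sorted(unknown)}")
    rows = []
    for taxon, ev in events.per_taxon_events.items():
        label = annotations.get(taxon)
        if keep is not None and label not in keep_set:
            continue
        for (parent, child), kind in ev.items():
            rows.append({
                "parent": parent, "child": child, "taxon": taxon,
                "event": kind, "annotation": label,
            })
    return pd.DataFrame(rows, columns=["parent", "child", "taxon", "event",
                                       "annotation"])
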