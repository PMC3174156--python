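"""Binding-site definitions, positive labelling, and ROC/AUC evaluation.

A probe location counts as a positive when it covers strictly more than a
given fraction of the residues of at least one biological site (0.8 for
annotated catalytic residues, 0.4 for ligand-contact binding sites).
The ROC is swept over distinct score thresholds; AUC uses the trapezoid
rule and equals the Mann–Whitney statistic with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from bindlev.structure_io import CalphaStructure, HeavyStructure, LigandRecord

__all__ = [
    "BindingSite",
    "RocResult",
    "site_from_ligand",
    "parse_annotation",
    "label_positives",
    "roc_auc",
    "evaluate_protein",
]


@dataclass(frozen=True)
class BindingSite:
    """A set of residue handles constituting one biological site."""

    residues: frozenset
    label: str
    source: str = "annotation"  # "ligand-contact" or "annotation"

    def __post_init__(self) -> None:
        residues = frozenset(int(r) for r in self.residues)
        if not residues:
            raise ValueError(f"binding site {self.label!r} is empty")
        object.__setattr__(self, "residues", residues)


@dataclass(frozen=True)
class RocResult:
    """ROC points (FPR, TPR) and the area under the curve."""

    points: np.ndarray  # (T, 2): fpr, tpr; starts (0,0), ends (1,1)
    auc: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        if np.any(np.diff(points, axis=0) < -1e-12):
            raise ValueError("ROC points must be monotone non-decreasing")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")
        object.__setattr__(self, "points", points)


def site_from_ligand(
    full_structure: HeavyStructure, ligand: LigandRecord, cutoff: float = 3.5
) -> BindingSite:
    """Residues with at least one heavy atom within ``cutoff`` Å of the ligand."""
    tree = cKDTree(ligand.heavy_atom_coords)
    dmin, _ = tree.query(full_structure.coords)
    residues = frozenset(
        int(r) for r in np.unique(full_structure.residue_index[dmin <= cutoff])
    )
    if not residues:
        raise ValueError(
            f"ligand {ligand.het_code} (chain {ligand.chain_id}) contacts no "
            f"residue within {cutoff} Å"
        )
    return BindingSite(residues=residues, label=ligand.het_code, source="ligand-contact")


def parse_annotation(text: str, structure: CalphaStructure) -> list[BindingSite]:
    """Parse a plain-text site annotation into BindingSites.

    One residue per line: ``chain res_seq [icode] [site_group]``; a missing
    group column puts the residue in the default group ``site1``.  Residues
    are resolved against ``structure`` by (chain, res_seq, icode).
    """
    handle_of = {key: i for i, key in enumerate(structure.residue_keys())}
    # icode-insensitive fallback for the common blank-icode case
    loose = {}
    for (c, s, i), h in handle_of.items():
        loose.setdefault((c, s), h)
    groups: dict[str, set[int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"annotation line {lineno}: need 'chain res_seq'")
        chain, res_seq = fields[0], int(fields[1])
        icode, group = "", "site1"
        rest = fields[2:]
        if rest and not rest[0].isdigit() and len(rest[0]) == 1 and rest[0].isalpha() and len(rest) > 1:
            icode, group = rest[0], rest[1]
        elif rest:
            group = rest[0]
        handle = handle_of.get((chain, res_seq, icode), loose.get((chain, res_seq)))
        if handle is None:
            raise ValueError(
                f"annotation line {lineno}: residue {chain}{res_seq}{icode} "
                "not present in structure"
            )
        groups.setdefault(group, set()).add(handle)
    return [
        BindingSite(residues=frozenset(res), label=name, source="annotation")
        for name, res in sorted(groups.items())
    ]


def label_positives(
    locations: Sequence, sites: Sequence[BindingSite], fraction: float
) -> np.ndarray:
    """Boolean labels: positive iff a location covers strictly more than
    ``fraction`` of the residues of some site (0.8 catalytic, 0.4 ligand)."""
    if not sites:
        raise ValueError("no binding sites to label against")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    labels = np.zeros(len(locations), dtype=bool)
    for k, loc in enumerate(locations):
        residues = set(getattr(loc, "residues", loc))
        for site in sites:
            if len(residues & site.residues) / len(site.residues) > fraction:
                labels[k] = True
                break
    return labels


def matched_sites(
    locations: Sequence, sites: Sequence[BindingSite], fraction: float
) -> list[bool]:
    """Per-site flag: was the site covered above ``fraction`` by any location?"""
    out = []
    for site in sites:
        hit = any(
            len(set(getattr(loc, "residues", loc)) & site.residues) / len(site.residues)
            > fraction
            for loc in locations
        )
        out.append(hit)
    return out


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC by threshold sweep over distinct scores; trapezoid AUC.

    Requires at least one positive and one negative.  Ties contribute half,
    so the AUC equals the normalized Mann–Whitney U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC needs both classes (got {n_pos} positives, {n_neg} negatives)"
        )
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # cut after each run of equal scores
    distinct = np.flatnonzero(np.diff(s) != 0)
    cuts = np.concatenate([distinct + 1, [len(s)]])
    tp = np.cumsum(y)[cuts - 1]
    fp = cuts - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    points = np.stack([fpr, tpr], axis=1)
    return RocResult(points=points, auc=auc, n_pos=n_pos, n_neg=n_neg)


@dataclass
class EvaluationReport:
    """Per-measure AUC report averaged over replicate docking runs."""

    auc: dict[str, float] = field(default_factory=dict)
    replicate_auc: dict[str, list[float]] = field(default_factory=dict)
    n_locations: list[int] = field(default_factory=list)
    n_positives: list[int] = field(default_factory=list)
    probed_sites: str = ""
    unmatched_sites: list[str] = field(default_factory=list)
    lc_graph_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "replicate_auc": self.replicate_auc,
            "n_locations": self.n_locations,
            "n_positives": self.n_positives,
            "probed_sites": self.probed_sites,
            "unmatched_sites": self.unmatched_sites,
            "lc_graph_fallback": self.lc_graph_fallback,
        }


def evaluate_protein(
    protein: CalphaStructure,
    sites: Sequence[BindingSite],
    config,
    measures: Iterable[str] = ("L_LF10", "L_FM5", "L_delta", "LC"),
    dx=None,
    heavy: HeavyStructure | None = None,
    enm_params=None,
    positive_fraction: float = 0.4,
    n_replicates: int = 2,
    amplitude: float = 1.0,
    master_seed: int = 0,
) -> EvaluationReport:
    """Full-pipeline AUC evaluation, averaged over replicate docking runs.

    Each replicate generates probe locations, scores them by LC, merges
    redundant ones at Jaccard 0.7, scores the survivors by the requested
    measures and computes one AUC per measure against ``sites``.  ``L_delta``
    and ``L_FM5`` require the difference vector ``dx``.
    """
    import bindlev.elastic_modes as elastic_modes
    import bindlev.leverage as leverage
    import bindlev.local_closeness as local_closeness
    import bindlev.probe_docking as probe_docking
    import bindlev.site_catalog as site_catalog

    measures = list(measures)
    if not sites:
        raise ValueError("no binding sites supplied")
    needs_dx = {"L_delta", "L_FM5"} & set(measures)
    if needs_dx and dx is None:
        raise ValueError(f"measures {sorted(needs_dx)} require a difference vector")
    report = EvaluationReport()
    modes = None
    if {"L_LF10", "L_FM5"} & set(measures):
        modes = elastic_modes.build_modes(protein, enm_params)
    if heavy is not None:
        graph = local_closeness.build_residue_graph(heavy)
    else:
        graph = local_closeness.build_residue_graph_calpha(protein)
        report.lc_graph_fallback = True
    lc_values = local_closeness.local_closeness(graph)

    subsets = {}
    if "L_LF10" in measures:
        subsets["L_LF10"] = elastic_modes.select_modes(modes, "LF10")
    if "L_FM5" in measures:
        subsets["L_FM5"] = elastic_modes.select_modes(modes, "FM5", dx=dx)

    matched_any = None
    for rep in range(n_replicates):
        rep_config = config.with_seed(master_seed + 1000003 * rep)
        locations = probe_docking.generate_probe_locations(protein, rep_config)
        if not locations:
            raise RuntimeError("docking produced no non-empty probe locations")
        lc_scores = [
            local_closeness.score_location_lc(loc.residues, lc_values)
            for loc in locations
        ]
        locations, lc_scores = site_catalog.merge_locations(locations, lc_scores)
        labels = label_positives(locations, sites, positive_fraction)
        hits = matched_sites(locations, sites, positive_fraction)
        matched_any = (
            hits if matched_any is None else [a or b for a, b in zip(matched_any, hits)]
        )
        report.n_locations.append(len(locations))
        report.n_positives.append(int(labels.sum()))
        for measure in measures:
            if measure == "LC":
                scores = lc_scores
            elif measure == "L_delta":
                scores = [
                    leverage.leverage_from_difference(loc, protein, dx, amplitude).value
                    for loc in locations
                ]
            else:
                scores = [
                    leverage.binding_leverage(
                        loc, protein, modes, subsets[measure], amplitude, measure
                    ).value
                    for loc in locations
                ]
            result = roc_auc(scores, labels)
            report.replicate_auc.setdefault(measure, []).append(result.auc)
    for measure in measures:
        report.auc[measure] = float(np.mean(report.replicate_auc[measure]))
    n_matched = sum(matched_any)
    report.probed_sites = f"{n_matched}/{len(sites)}"
    report.unmatched_sites = [
        site.label for site, hit in zip(sites, matched_any) if not hit
    ]
    return report
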