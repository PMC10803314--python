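"""Comparative characterization of detected elements.

Subfamilies are defined by global pairwise nucleotide identity (default
threshold 0.90, single linkage over the identity graph); gene families by
reciprocal best hits between element proteomes (20% identity, 50% coverage
defaults); and the gene adjacent to the integrase is typed as *iolg*
(integrase-overlapping gene), *icg* (contiguous gene) or absent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from ._align import alignment_identity, dna_global_aligner, protein_local_aligner
from .detect import PicmiElement


@dataclass
class SubfamilyParams:
    identity_threshold: float = 0.90
    linkage: str = "single"
    strict: bool = False  # True: identity must exceed the threshold to link

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.linkage not in {"single", "complete"}:
            raise ValueError("linkage must be 'single' or 'complete'")


@dataclass
class GeneFamilyParams:
    min_identity: float = 0.20
    min_coverage: float = 0.50

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_coverage):
            if not (0 < v <= 1):
                raise ValueError("thresholds must be in (0, 1]")


@dataclass
class IntNeighborCall:
    category: str  # iolg | icg | absent
    overlap_nt: int = 0
    overlap_motif: str = ""

    def __post_init__(self) -> None:
        if self.category == "iolg" and self.overlap_nt < 1:
            raise ValueError("iolg requires overlap_nt >= 1")
        if self.category != "iolg" and (self.overlap_nt != 0 or self.overlap_motif):
            raise ValueError("non-iolg calls carry no overlap")


@dataclass
class SubfamilyAssignment:
    element_ids: list[str]
    labels: dict[str, int]
    identity_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def n_subfamilies(self) -> int:
        return len(set(self.labels.values()))


def pairwise_identity(
    a: str,
    b: str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Global nucleotide identity: matches over alignment columns, gap
    columns included in the denominator. Symmetric by construction."""
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    aligner = dna_global_aligner(match, mismatch, gap_open, gap_extend)
    return alignment_identity(aligner.align(a, b)[0])


def identity_matrix(seqs: Sequence[str]) -> np.ndarray:
    n = len(seqs)
    mat = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = pairwise_identity(seqs[i], seqs[j])
    return mat


def _dense_labels(raw_labels: Sequence[int], ids: Sequence[str]) -> dict[str, int]:
    """Renumber cluster labels: descending size, ties by first element id."""
    groups: dict[int, list[str]] = {}
    for lab, eid in zip(raw_labels, ids):
        groups.setdefault(lab, []).append(eid)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    out: dict[str, int] = {}
    for new_id, members in enumerate(ordered):
        for eid in members:
            out[eid] = new_id
    return out


def cluster_subfamilies(
    elements: Mapping[str, str] | Sequence[str],
    params: Optional[SubfamilyParams] = None,
    *,
    precomputed: Optional[np.ndarray] = None,
) -> SubfamilyAssignment:
    """Partition element sequences into subfamilies at the identity threshold.

    ``elements`` maps element_id -> sequence (a bare sequence list gets ids
    e0, e1, ...). Single linkage takes connected components of the graph with
    edges at identity >= threshold; complete linkage agglomerates on
    1 - identity distances.
    """
    params = params or SubfamilyParams()
    if not isinstance(elements, Mapping):
        elements = {f"e{i}": s for i, s in enumerate(elements)}
    ids = list(elements)
    if not ids:
        raise ValueError("need at least one element")
    mat = precomputed if precomputed is not None else identity_matrix(
        [elements[i] for i in ids]
    )
    thr = params.identity_threshold
    if params.strict:
        adj = mat > thr
    else:
        adj = mat >= thr
    if len(ids) == 1:
        return SubfamilyAssignment(ids, {ids[0]: 0}, mat)
    if params.linkage == "single":
        _, raw = connected_components(csr_matrix(adj), directed=False)
    else:
        dist = squareform(1.0 - mat, checks=False)
        tree = scipy_linkage(dist, method="complete")
        cut = (1.0 - thr) + (0 if params.strict else 1e-12)
        raw = fcluster(tree, t=cut, criterion="distance")
    return SubfamilyAssignment(ids, _dense_labels(raw, ids), mat)


def _local_hit(aligner, query: str, target: str):
    """Best local alignment stats: (score, identity, query_cov, target_cov)."""
    alns = aligner.align(query, target)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    columns = aln.length
    if columns == 0:
        return None
    ident = counts.identities / columns
    q_span = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    t_span = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    return aln.score, ident, q_span / len(query), t_span / len(target)


def rbh_gene_families(
    proteomes: Mapping[str, Mapping[str, str]],
    params: Optional[GeneFamilyParams] = None,
) -> dict[str, int]:
    """Cluster proteins into families by reciprocal best hits.

    ``proteomes`` maps element_id -> {protein_id -> sequence}; protein ids
    must be globally unique. A hit is valid when local identity >= 20% and
    both query and target coverage >= 50% (defaults); the best hit per
    (query, target proteome) is chosen by score, ties by identity then
    lexicographic protein id. Reciprocal best hits form edges; families are
    connected components, with unpaired proteins as singletons. Output is
    invariant to input order.
    """
    params = params or GeneFamilyParams()
    aligner = protein_local_aligner()
    element_ids = sorted(proteomes)
    all_proteins: list[tuple[str, str]] = []  # (protein_id, element_id)
    seqs: dict[str, str] = {}
    for eid in element_ids:
        for pid in sorted(proteomes[eid]):
            if pid in seqs:
                raise ValueError(f"duplicate protein id {pid}")
            seqs[pid] = proteomes[eid][pid]
            all_proteins.append((pid, eid))

    best: dict[tuple[str, str], str] = {}  # (query_pid, target_element) -> target_pid
    for qpid, qeid in all_proteins:
        for teid in element_ids:
            if teid == qeid:
                continue
            best_key = None
            best_pid = None
            for tpid in sorted(proteomes[teid]):
                hit = _local_hit(aligner, seqs[qpid], seqs[tpid])
                if hit is None:
                    continue
                score, ident, qcov, tcov = hit
                if ident < params.min_identity or qcov < params.min_coverage or tcov < params.min_coverage:
                    continue
                key = (-score, -ident, tpid)
                if best_key is None or key < best_key:
                    best_key, best_pid = key, tpid
            if best_pid is not None:
                best[(qpid, teid)] = best_pid

    pids = [p for p, _ in all_proteins]
    index = {p: i for i, p in enumerate(pids)}
    eid_of = dict(all_proteins)
    rows, cols = [], []
    for (qpid, teid), tpid in best.items():
        if best.get((tpid, eid_of[qpid])) == qpid:
            rows.append(index[qpid])
            cols.append(index[tpid])
    n = len(pids)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, raw = connected_components(graph, directed=False)
    return _dense_labels(raw, pids)


def classify_int_neighbor(element: PicmiElement) -> IntNeighborCall:
    """Type the gene between *int* and *alpA* on an extracted element.

    ``iolg`` when its coordinates overlap *int* (>= 1 nt, motif reported
    5'->3' on the fis-forward element strand), ``icg`` when a gene lies
    between them without overlapping *int*, ``absent`` when none does.
    """
    roles = element.role_features
    if "int" not in roles or "alpA" not in roles:
        raise ValueError("element lacks int or alpA coordinates")
    intg, alpa = roles["int"], roles["alpA"]
    if alpa.start <= intg.start:
        gap_lo, gap_hi = alpa.end, intg.start
    else:
        gap_lo, gap_hi = intg.end, alpa.start
    between = [
        f
        for f in element.internal
        if f.gene_id not in {intg.gene_id, alpa.gene_id}
        and f.end > gap_lo
        and f.start < gap_hi
    ]
    if not between:
        return IntNeighborCall("absent")
    neighbor = min(
        between, key=lambda f: min(abs(f.end - intg.start), abs(intg.end - f.start))
    )
    ov = neighbor.overlap(intg.start, intg.end)
    if ov >= 1:
        lo_ov = max(neighbor.start, intg.start)
        motif = element.element_seq[lo_ov : lo_ov + ov]
        return IntNeighborCall("iolg", overlap_nt=ov, overlap_motif=motif)
    return IntNeighborCall("icg")


def core_accessory_table(
    proteomes: Mapping[str, Mapping[str, str]],
    families: Mapping[str, int],
) -> tuple[list[dict], list[dict]]:
    """Summarize gene families across elements.

    Returns (family_rows, element_rows): per family the presence count and a
    core flag (present in every element); per element its ordered
    gene-family string for synteny display (protein order follows the sorted
    protein ids within each proteome).
    """
    n_elements = len(proteomes)
    members: dict[int, set[str]] = {}
    eid_of = {
        pid: eid for eid, prots in proteomes.items() for pid in prots
    }
    for pid, fam in families.items():
        members.setdefault(fam, set()).add(eid_of[pid])
    family_rows = [
        {
            "family_id": fam,
            "n_elements": len(present),
            "core": len(present) == n_elements,
            "n_proteins": sum(1 for p, f in families.items() if f == fam),
        }
        for fam, present in sorted(members.items())
    ]
    element_rows = [
        {
            "element_id": eid,
            "family_string": "-".join(
                str(families[pid]) for pid in sorted(proteomes[eid])
            ),
        }
        for eid in sorted(proteomes)
    ]
    return family_rows, element_rows
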