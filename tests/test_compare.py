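"""Subfamily clustering, RBH gene families and int-neighbor typing."""

import itertools

import numpy as np
import pytest

from picmi import (
    GeneFamilyParams,
    SimulationConfig,
    SubfamilyParams,
    classify_int_neighbor,
    cluster_subfamilies,
    core_accessory_table,
    detect_elements,
    generate_genome,
    mutate_element,
    pairwise_identity,
    rbh_gene_families,
    simulate_subfamily_elements,
)
from picmi._align import protein_local_aligner
from picmi.compare import _local_hit
from picmi.detect import DetectionModel
from picmi.simulate import random_dna

AA = "ACDEFGHIKLMNPQRSTVWY"


def mutate_protein(rng, seq, divergence):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < divergence:
            out[i] = AA[rng.integers(0, 20)]
    return "".join(out)


# ---------------------------------------------------------------- identity


def test_identity_of_identical_sequences(rng):
    s = random_dna(rng, 400)
    assert pairwise_identity(s, s) == 1.0


def test_identity_with_known_substitution_count(rng):
    """50 substitutions in 1000 bp without indels force identity 0.95."""
    a = random_dna(rng, 1000)
    b = list(a)
    positions = rng.choice(1000, size=50, replace=False)
    for p in positions:
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    assert pairwise_identity(a, "".join(b)) == pytest.approx(0.95, abs=1e-9)


def test_identity_is_symmetric(rng):
    for _ in range(5):
        a = random_dna(rng, 300)
        b = mutate_element(a, 0.1, np.random.default_rng(rng.integers(2**31)))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a), abs=1e-12)


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT")


# ---------------------------------------------------------------- clustering


def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1 :]
        yield [[first]] + part


def oracle_single_linkage(mat, thr):
    """Unique partition where blocks are connected and no cross-block edge,
    found by exhaustive enumeration."""
    n = len(mat)
    for part in _partitions(list(range(n))):
        ok = True
        for block in part:
            if len(block) > 1:
                # connected within the block?
                seen = {block[0]}
                frontier = [block[0]]
                while frontier:
                    x = frontier.pop()
                    for y in block:
                        if y not in seen and mat[x][y] >= thr:
                            seen.add(y)
                            frontier.append(y)
                if seen != set(block):
                    ok = False
                    break
        if ok:
            for b1, b2 in itertools.combinations(part, 2):
                if any(mat[x][y] >= thr for x in b1 for y in b2):
                    ok = False
                    break
        if ok:
            return frozenset(frozenset(b) for b in part)
    raise AssertionError("no valid partition found")


def labels_to_partition(labels):
    blocks = {}
    for i, (eid, lab) in enumerate(sorted(labels.items())):
        blocks.setdefault(lab, set()).add(i)
    return frozenset(frozenset(b) for b in blocks.values())


def test_three_element_example():
    mat = np.array([[1.0, 0.95, 0.80], [0.95, 1.0, 0.80], [0.80, 0.80, 1.0]])
    asn = cluster_subfamilies({"A": "x", "B": "x", "C": "x"}, precomputed=mat)
    assert asn.labels["A"] == asn.labels["B"] != asn.labels["C"]


def test_identical_elements_form_one_subfamily(rng):
    s = random_dna(rng, 200)
    asn = cluster_subfamilies([s] * 4)
    assert asn.n_subfamilies == 1


@pytest.mark.parametrize("identity,expect_clusters", [(0.89, 2), (0.91, 1)])
def test_threshold_straddling(identity, expect_clusters):
    mat = np.array([[1.0, identity], [identity, 1.0]])
    asn = cluster_subfamilies({"a": "x", "b": "x"}, precomputed=mat)
    assert asn.n_subfamilies == expect_clusters


def test_clustering_matches_partition_enumeration(rng):
    for n in (3, 5, 6):
        for _ in range(10):
            mat = np.eye(n)
            for i, j in itertools.combinations(range(n), 2):
                mat[i, j] = mat[j, i] = rng.choice([0.5, 0.85, 0.92, 0.99])
            ids = {f"e{i}": "x" for i in range(n)}
            asn = cluster_subfamilies(ids, precomputed=mat)
            assert labels_to_partition(asn.labels) == oracle_single_linkage(mat, 0.90)


def test_raising_threshold_refines_partitions(rng):
    n = 7
    mat = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = rng.uniform(0.7, 1.0)
    ids = {f"e{i}": "x" for i in range(n)}
    low = cluster_subfamilies(ids, SubfamilyParams(identity_threshold=0.85), precomputed=mat)
    high = cluster_subfamilies(ids, SubfamilyParams(identity_threshold=0.95), precomputed=mat)
    # every high-threshold cluster sits inside one low-threshold cluster
    for block in labels_to_partition(high.labels):
        containers = {
            frozenset(b) for b in labels_to_partition(low.labels) if block & b
        }
        assert len(containers) == 1


def test_planted_subfamilies_recovered_exactly():
    cfg = SimulationConfig(
        seed=77, n_subfamilies=3, element_len=1200,
        within_subfamily_divergence=0.03, between_subfamily_divergence=0.20,
    )
    seqs, truth_labels = simulate_subfamily_elements(cfg, members_per_subfamily=2)
    asn = cluster_subfamilies(seqs)
    assert asn.n_subfamilies == 3
    for a, b in itertools.combinations(seqs, 2):
        same_truth = truth_labels[a] == truth_labels[b]
        assert (asn.labels[a] == asn.labels[b]) == same_truth


# ---------------------------------------------------------------- RBH


def random_protein(rng, n):
    return "M" + "".join(AA[i] for i in rng.integers(0, 20, size=n - 1))


def oracle_rbh(proteomes, params):
    """Independent reciprocal-best-hit construction with the same scorer."""
    aligner = protein_local_aligner()
    seqs = {p: s for prots in proteomes.values() for p, s in prots.items()}
    eid_of = {p: e for e, prots in proteomes.items() for p in prots}

    def best_hit(q, te):
        scored = []
        for t in sorted(proteomes[te]):
            hit = _local_hit(aligner, seqs[q], seqs[t])
            if hit is None:
                continue
            score, ident, qc, tc = hit
            if ident >= params.min_identity and qc >= params.min_coverage and tc >= params.min_coverage:
                scored.append((-score, -ident, t))
        return min(scored)[2] if scored else None

    edges = set()
    for q in seqs:
        for te in proteomes:
            if te == eid_of[q]:
                continue
            t = best_hit(q, te)
            if t is not None and best_hit(t, eid_of[q]) == q:
                edges.add(frozenset({q, t}))
    # manual BFS components
    comp = {}
    for p in sorted(seqs):
        if p in comp:
            continue
        group = {p}
        frontier = [p]
        while frontier:
            x = frontier.pop()
            for e in edges:
                if x in e:
                    (y,) = e - {x}
                    if y not in group:
                        group.add(y)
                        frontier.append(y)
        for m in group:
            comp[m] = min(group)
    return comp


def families_to_partition(families):
    blocks = {}
    for pid, fam in families.items():
        blocks.setdefault(fam, set()).add(pid)
    return frozenset(frozenset(b) for b in blocks.values())


def make_proteome_pair(rng, n_genes=4, divergence=0.4):
    p1 = {f"A_{i}": random_protein(rng, int(rng.integers(80, 160))) for i in range(n_genes)}
    p2 = {
        f"B_{i}": mutate_protein(rng, p1[f"A_{i}"], divergence) for i in range(n_genes)
    }
    return {"A": p1, "B": p2}


def test_orthologs_paired_exactly(rng):
    proteomes = make_proteome_pair(rng, n_genes=4, divergence=0.4)
    fams = rbh_gene_families(proteomes)
    for i in range(4):
        assert fams[f"A_{i}"] == fams[f"B_{i}"]
    assert len(set(fams.values())) == 4


def test_rbh_matches_oracle(rng):
    for _ in range(3):
        proteomes = make_proteome_pair(rng, n_genes=3, divergence=0.5)
        fams = rbh_gene_families(proteomes)
        oracle = oracle_rbh(proteomes, GeneFamilyParams())
        assert families_to_partition(fams) == families_to_partition(oracle)


def test_single_proteome_gives_singletons(rng):
    proteomes = {"only": {f"p{i}": random_protein(rng, 100) for i in range(5)}}
    fams = rbh_gene_families(proteomes)
    assert len(set(fams.values())) == 5


def test_low_identity_ortholog_stays_singleton(rng):
    base = random_protein(rng, 150)
    proteomes = {
        "A": {"A_0": base},
        "B": {"B_0": mutate_protein(rng, base, 0.9)},  # ~5-15% identity left
    }
    fams = rbh_gene_families(proteomes)
    assert fams["A_0"] != fams["B_0"]


def test_rbh_invariant_to_input_order(rng):
    proteomes = make_proteome_pair(rng, n_genes=4, divergence=0.45)
    reversed_inner = {
        e: dict(reversed(list(prots.items()))) for e, prots in reversed(list(proteomes.items()))
    }
    assert families_to_partition(rbh_gene_families(proteomes)) == families_to_partition(
        rbh_gene_families(reversed_inner)
    )


# ---------------------------------------------------------------- int neighbor


@pytest.mark.parametrize(
    "order,overlap,category",
    [
        (("fis", "up2", "prim", "up1", "alpA", "iolg", "int"), 4, "iolg"),
        (("fis", "up2", "prim", "up1", "alpA", "iolg", "int"), 1, "iolg"),
        (("fis", "up2", "prim", "up1", "alpA", "iolg", "int"), 13, "iolg"),
        (("fis", "up2", "prim", "up1", "alpA", "iolg", "int"), 0, "icg"),
        (("fis", "up2", "prim", "up1", "alpA", "int"), 0, "absent"),
    ],
)
def test_int_neighbor_typing(order, overlap, category):
    cfg = SimulationConfig(seed=55, gene_order=order, iolg_overlap_nt=overlap)
    genome, truth = generate_genome(cfg, 0)
    elements, _ = detect_elements(genome, DetectionModel(), truth.fis_protein)
    call = classify_int_neighbor(elements[0])
    assert call.category == category
    assert call.overlap_nt == (overlap if category == "iolg" else 0)
    if category == "iolg":
        assert call.overlap_motif == truth.iolg_motif
        if overlap == 4:
            assert call.overlap_motif == "ATGA"


def test_iolg_overlap_preserved_on_minus_strand():
    cfg = SimulationConfig(seed=56, element_strand="-")
    genome, truth = generate_genome(cfg, 0)
    elements, _ = detect_elements(genome, DetectionModel(), truth.fis_protein)
    call = classify_int_neighbor(elements[0])
    assert (call.category, call.overlap_nt, call.overlap_motif) == ("iolg", 4, "ATGA")


# ---------------------------------------------------------------- core/accessory


def test_core_accessory_presence_counts():
    families = {"A_int": 0, "B_int": 0, "A_x": 1, "B_y": 2}
    proteomes = {"A": {"A_int": "M", "A_x": "M"}, "B": {"B_int": "M", "B_y": "M"}}
    fam_rows, el_rows = core_accessory_table(proteomes, families)
    by_id = {r["family_id"]: r for r in fam_rows}
    assert by_id[0]["core"] and by_id[0]["n_elements"] == 2
    assert not by_id[1]["core"] and by_id[1]["n_elements"] == 1
    assert {r["element_id"] for r in el_rows} == {"A", "B"}
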