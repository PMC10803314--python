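"""Seeded generators for genomes with planted minimalist satellites, decoy
loci, divergence-controlled element variants and simulated read sets.

The planted element reproduces the architecture of the reference satellite:
a ~6.1 kb region starting at the host *fis* gene with gene order
fis - up2 - prim - up1 - alpA - iolg - int, flanked by exact 17 bp direct
repeats, with the *iolg* gene overlapping *int* by a configurable 1/4/13 nt
(the 4 nt overlap spells ATGA: the *int* start codon read through *iolg*'s
stop). Decoy loci exercise each exclusion filter. Every generated entity is
recorded in a planted-truth object so recovery tests can compare exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genome import AnnotatedGenome, Contig, GeneFeature
from .packaging import PackagingCounts

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# fixed per-role ORF lengths, nt including the stop codon
_ROLE_NT = {
    "fis": 297,
    "zntR": 303,
    "int": 1203,
    "alpA": 303,
    "prim": 903,
    "iolg": 303,
    "up1": 252,
    "up2": 252,
    "filler": 402,
}
_ROLE_DOMAINS = {
    "int": frozenset({"PF00589"}),
    "alpA": frozenset({"PF05930"}),
    "prim": frozenset({"PF13148"}),
    "fis": frozenset({"PF02954"}),
}


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults mirror the reference
    helper/satellite system (47,851 bp helper, 6,110 bp element, 17 bp
    repeats, ATGA 4 nt iolg overlap, 8-copy concatemer)."""

    seed: int = 0
    n_genomes: int = 1
    element_len: int = 6110
    repeat_len: int = 17
    gene_order: tuple[str, ...] = ("fis", "up2", "prim", "up1", "alpA", "iolg", "int")
    iolg_overlap_nt: int = 4
    plant_element: bool = True
    element_strand: str = "+"
    decoys: frozenset[str] = frozenset()
    within_subfamily_divergence: float = 0.03
    between_subfamily_divergence: float = 0.20
    n_subfamilies: int = 1
    helper_len: int = 47851
    hitchhiker_fraction: float = 0.15
    concatemer_copies: int = 8
    n_reads: int = 100_000
    read_len: int = 150
    long_read_len_mean: int = 20_000
    chimera_rate: float = 1e-4
    max_gene_gap: int = 5
    small_orf_aa: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.iolg_overlap_nt not in {0, 1, 4, 13}:
            raise ValueError("iolg_overlap_nt must be one of 0, 1, 4, 13")
        if not (0 <= self.within_subfamily_divergence < 1):
            raise ValueError("divergence must be in [0, 1)")
        bad = self.decoys - {"other_family", "scattered_cores", "cross_contig"}
        if bad:
            raise ValueError(f"unknown decoys: {bad}")


@dataclass
class GenomeTruth:
    """Complete bookkeeping of everything planted in one genome."""

    genome_id: str
    element_planted: bool = False
    element_contig: str = ""
    element_start: int = 0
    element_end: int = 0
    element_seq: str = ""
    repeat_seq: str = ""
    repeat_left: int = -1
    repeat_right: int = -1
    roles: dict[str, str] = field(default_factory=dict)
    iolg_overlap_nt: int = 0
    iolg_motif: str = ""
    fis_protein: str = ""
    subfamily: int = 0
    decoys: dict[str, str] = field(default_factory=dict)  # decoy kind -> contig
    gene_records: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    small_orfs: list[tuple[int, int, str]] = field(default_factory=list)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


_COMP = str.maketrans("ACGT", "TGCA")


def _other_base(b: str) -> str:
    return "ACGT"[("ACGT".index(b) + 1) % 4]


def random_orf(rng: np.random.Generator, nt_len: int, *, second_codon_a: bool = False) -> str:
    """ATG-initiated, stop-terminated ORF; ``nt_len`` must be a multiple of 3."""
    if nt_len % 3 or nt_len < 9:
        raise ValueError("ORF length must be a multiple of 3, >= 9")
    n_codons = nt_len // 3 - 2
    codons = []
    for i in range(n_codons):
        while True:
            c = random_dna(rng, 3)
            if c not in _STOPS and c != "ATG":
                break
        if i == 0 and second_codon_a:
            c = "A" + c[1:]
        codons.append(c)
    return "ATG" + "".join(codons) + _STOPS[rng.integers(0, 3)]


class _ContigBuilder:
    def __init__(self, contig_id: str):
        self.contig_id = contig_id
        self.parts: list[str] = []
        self.cursor = 0
        self.features: list[GeneFeature] = []

    def add_seq(self, seq: str) -> int:
        start = self.cursor
        self.parts.append(seq)
        self.cursor += len(seq)
        return start

    def add_gene(
        self,
        gene_id: str,
        seq: str,
        *,
        strand: str = "+",
        domains: frozenset[str] = frozenset(),
        product: Optional[str] = None,
        overlap_prev: int = 0,
    ) -> GeneFeature:
        if overlap_prev:
            # the overlapping bases are taken from this gene's 5' end
            self.parts[-1] = self.parts[-1][:-overlap_prev]
            self.cursor -= overlap_prev
        start = self.add_seq(seq)
        feat = GeneFeature(
            gene_id=gene_id,
            contig_id=self.contig_id,
            start=start,
            end=start + len(seq),
            strand=strand,
            domain_labels=domains,
            product_label=product,
        )
        self.features.append(feat)
        return feat

    def build(self) -> tuple[Contig, list[GeneFeature]]:
        return Contig(self.contig_id, "".join(self.parts)), self.features


def _build_element_region(
    rng: np.random.Generator,
    config: SimulationConfig,
    fis_seq: str,
    interior_seqs: Optional[dict[str, str]] = None,
) -> tuple[str, list[tuple[str, int, int, str]], dict]:
    """Assemble the element region (fis start .. attR end) on the forward
    strand. Returns (sequence, features as (role, start, end, strand),
    info dict with repeat/orf positions)."""
    order = config.gene_order
    if order[0] != "fis" or order[-1] != "int":
        raise ValueError("gene_order must start with fis and end with int")
    gap = 20
    repeat = random_dna(rng, config.repeat_len)
    seqs = dict(interior_seqs or {})
    for role in order[1:]:
        if role not in seqs:
            seqs[role] = random_orf(
                rng, _ROLE_NT.get(role, 303), second_codon_a=(role == "int")
            )
    spacer_host = "prim" if "prim" in order[1:-1] else order[0]
    # fixed layout length with a zero-length spacer
    fixed = len(fis_seq) + 10 + config.repeat_len + 6 + config.repeat_len
    prev = order[0]
    for role in order[1:]:
        overlapping = role == "int" and prev == "iolg" and config.iolg_overlap_nt > 0
        fixed += (0 if overlapping else gap) + len(seqs[role])
        fixed -= config.iolg_overlap_nt if overlapping else 0
        prev = role
    spacer_len = config.element_len - fixed
    if spacer_len < 0:
        raise ValueError(
            f"element_len {config.element_len} too small for planted genes "
            f"({fixed} bp minimum)"
        )
    spacer = list(random_dna(rng, spacer_len))
    orf_positions: list[tuple[int, int, str]] = []
    off = 30
    for aa in config.small_orf_aa:
        orf = random_orf(rng, 3 * aa + 3)  # aa residues + stop codon
        if off + len(orf) + 10 > spacer_len:
            raise ValueError("spacer too small for requested small ORFs")
        spacer[off : off + len(orf)] = list(orf)
        orf_positions.append((off, off + len(orf), orf))
        off += len(orf) + 60
    spacer_seq = "".join(spacer)

    b = _ContigBuilder("element")
    feats: list[tuple[str, int, int, str]] = []
    f = b.add_gene("fis", fis_seq, product="fis")
    feats.append(("fis", f.start, f.end, "+"))
    b.add_seq(random_dna(rng, 10))
    attl = b.add_seq(repeat)
    spacer_start = -1
    prev = order[0]
    for role in order[1:]:
        overlapping = role == "int" and prev == "iolg" and config.iolg_overlap_nt > 0
        if not overlapping:
            b.add_seq(random_dna(rng, gap))
        if prev == spacer_host:
            # one large non-coding stretch absorbs the length budget
            spacer_start = b.add_seq(spacer_seq)
        f = b.add_gene(
            role, seqs[role], overlap_prev=config.iolg_overlap_nt if overlapping else 0
        )
        feats.append((role, f.start, f.end, "+"))
        prev = role
    b.add_seq(random_dna(rng, 6))
    attr = b.add_seq(repeat)
    contig, _ = b.build()
    seq = list(contig.seq)
    # sentinel bases so the planted repeat pair cannot extend by coincidence
    if seq[attl - 1] == seq[attr - 1]:
        seq[attr - 1] = _other_base(seq[attr - 1])
    info = {
        "repeat": repeat,
        "attl": attl,
        "attr": attr,
        "after_attl": seq[attl + config.repeat_len],
        "orfs": [(spacer_start + s, spacer_start + e, o) for s, e, o in orf_positions],
    }
    return "".join(seq), feats, info


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    return aa.rstrip("*")


def _revcomp(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())


def generate_genome(
    config: SimulationConfig,
    index: int = 0,
    *,
    fis_seq: Optional[str] = None,
    interior_seqs: Optional[dict[str, str]] = None,
    subfamily: int = 0,
) -> tuple[AnnotatedGenome, GenomeTruth]:
    """Generate one annotated genome with the configured element and decoys.

    ``fis_seq``/``interior_seqs`` allow a cohort generator to share the host
    anchor and plant divergence-controlled element variants. Output is a
    deterministic function of (config, index).
    """
    rng = np.random.default_rng([config.seed % (2**31), index])
    gid = f"sim{config.seed}_{index}"
    truth = GenomeTruth(genome_id=gid)
    if fis_seq is None:
        fis_seq = random_orf(rng, _ROLE_NT["fis"])
    truth.fis_protein = _translate(fis_seq)
    truth.subfamily = subfamily

    b = _ContigBuilder(f"{gid}_c1")
    contigs: list[Contig] = []
    features: list[GeneFeature] = []

    def bg_genes(builder: _ContigBuilder, n: int, tag: str) -> None:
        for k in range(n):
            builder.add_seq(random_dna(rng, int(rng.integers(80, 300))))
            builder.add_gene(
                f"{tag}{k}",
                random_orf(rng, _ROLE_NT["filler"]),
                strand="+" if rng.random() < 0.5 else "-",
            )

    bg_genes(b, 2, f"{gid}_bgA")
    b.add_seq(random_dna(rng, 200))
    b.add_gene(f"{gid}_zntR", random_orf(rng, _ROLE_NT["zntR"]), product="zntR")

    if config.plant_element:
        region_seq, region_feats, info = _build_element_region(
            rng, config, fis_seq, interior_seqs
        )
        # guard the contig base adjacent to attR against repeat extension
        pre = list(random_dna(rng, 30))
        if config.element_strand == "-":
            comp = info["after_attl"].translate(_COMP)
            if pre[-1] == comp:
                pre[-1] = _other_base(comp)
        b.add_seq("".join(pre))
        region_start = b.cursor
        if config.element_strand == "+":
            b.add_seq(region_seq)
            for role, s, e, st in region_feats:
                feat = GeneFeature(
                    gene_id=f"{gid}_{role}",
                    contig_id=b.contig_id,
                    start=region_start + s,
                    end=region_start + e,
                    strand=st,
                    domain_labels=_ROLE_DOMAINS.get(role, frozenset()),
                    product_label=role,
                )
                b.features.append(feat)
                truth.roles[role] = feat.gene_id
            truth.repeat_left = region_start + info["attl"]
            truth.repeat_right = region_start + info["attr"]
        else:
            n = len(region_seq)
            b.add_seq(_revcomp(region_seq))
            for role, s, e, st in region_feats:
                feat = GeneFeature(
                    gene_id=f"{gid}_{role}",
                    contig_id=b.contig_id,
                    start=region_start + n - e,
                    end=region_start + n - s,
                    strand="-" if st == "+" else "+",
                    domain_labels=_ROLE_DOMAINS.get(role, frozenset()),
                    product_label=role,
                )
                b.features.append(feat)
                truth.roles[role] = feat.gene_id
            truth.repeat_left = region_start + n - (info["attr"] + config.repeat_len)
            truth.repeat_right = region_start + n - (info["attl"] + config.repeat_len)
        truth.element_planted = True
        truth.element_contig = b.contig_id
        truth.element_start = region_start
        truth.element_end = region_start + len(region_seq)
        truth.element_seq = region_seq  # fis-forward orientation
        truth.repeat_seq = info["repeat"]
        truth.small_orfs = list(info["orfs"])  # fis-forward element coords
        truth.iolg_overlap_nt = (
            config.iolg_overlap_nt if "iolg" in config.gene_order else 0
        )
        if truth.iolg_overlap_nt:
            int_rel_start = next(s for r, s, e, _ in region_feats if r == "int")
            truth.iolg_motif = region_seq[
                int_rel_start : int_rel_start + truth.iolg_overlap_nt
            ]
        if config.element_strand == "+":
            post = list(random_dna(rng, 150))
            if post[0] == info["after_attl"]:
                post[0] = _other_base(post[0])
            b.add_seq("".join(post))
        else:
            b.add_seq(random_dna(rng, 150))
    else:
        b.add_seq(random_dna(rng, 180))
    bg_genes(b, 3, f"{gid}_bgB")

    if "scattered_cores" in config.decoys:
        # all four roles present but separated by > max_gene_gap genes
        for role in ("int", "alpA", "prim", "fis"):
            b.add_gene(
                f"{gid}_scat_{role}",
                random_orf(rng, _ROLE_NT[role]),
                domains=_ROLE_DOMAINS[role],
            )
            bg_genes(b, config.max_gene_gap + 1, f"{gid}_scat_{role}_fill")
        truth.decoys["scattered_cores"] = b.contig_id

    b.add_seq(random_dna(rng, 300))
    contig, feats = b.build()
    contigs.append(contig)
    features.extend(feats)

    if "other_family" in config.decoys:
        d = _ContigBuilder(f"{gid}_c_fam")
        d.add_seq(random_dna(rng, 400))
        d.add_gene(f"{gid}_fam_fis", fis_seq, domains=_ROLE_DOMAINS["fis"], product="fis")
        d.add_seq(random_dna(rng, 40))
        d.add_gene(f"{gid}_fam_terS", random_orf(rng, 453), product="terS")
        d.add_seq(random_dna(rng, 40))
        d.add_gene(f"{gid}_fam_int", random_orf(rng, _ROLE_NT["int"]), domains=_ROLE_DOMAINS["int"])
        d.add_seq(random_dna(rng, 40))
        d.add_gene(f"{gid}_fam_alpA", random_orf(rng, _ROLE_NT["alpA"]), domains=_ROLE_DOMAINS["alpA"])
        d.add_seq(random_dna(rng, 40))
        d.add_gene(f"{gid}_fam_prim", random_orf(rng, _ROLE_NT["prim"]), domains=_ROLE_DOMAINS["prim"])
        d.add_seq(random_dna(rng, 400))
        contig, feats = d.build()
        contigs.append(contig)
        features.extend(feats)
        truth.decoys["other_family"] = contig.id

    if "cross_contig" in config.decoys:
        d1 = _ContigBuilder(f"{gid}_c_x1")
        d1.add_seq(random_dna(rng, 300))
        d1.add_gene(f"{gid}_x_fis", fis_seq, domains=_ROLE_DOMAINS["fis"], product="fis")
        d1.add_seq(random_dna(rng, 40))
        d1.add_gene(f"{gid}_x_alpA", random_orf(rng, _ROLE_NT["alpA"]), domains=_ROLE_DOMAINS["alpA"])
        d1.add_seq(random_dna(rng, 300))
        d2 = _ContigBuilder(f"{gid}_c_x2")
        d2.add_seq(random_dna(rng, 300))
        d2.add_gene(f"{gid}_x_int", random_orf(rng, _ROLE_NT["int"]), domains=_ROLE_DOMAINS["int"])
        d2.add_seq(random_dna(rng, 40))
        d2.add_gene(f"{gid}_x_prim", random_orf(rng, _ROLE_NT["prim"]), domains=_ROLE_DOMAINS["prim"])
        d2.add_seq(random_dna(rng, 300))
        for d in (d1, d2):
            contig, feats = d.build()
            contigs.append(contig)
            features.extend(feats)
        truth.decoys["cross_contig"] = f"{gid}_c_x1,{gid}_c_x2"

    for f in features:
        truth.gene_records[f.gene_id] = (f.contig_id, f.start, f.end, f.strand)
    genome = AnnotatedGenome(genome_id=gid, contigs=contigs, features=features)
    return genome, truth


_COHORT_SCHEDULE = (
    dict(plant_element=True, decoys=frozenset()),
    dict(plant_element=True, decoys=frozenset({"other_family", "scattered_cores", "cross_contig"})),
    dict(plant_element=False, decoys=frozenset({"other_family"})),
    dict(plant_element=False, decoys=frozenset({"scattered_cores"})),
    dict(plant_element=True, decoys=frozenset({"cross_contig"})),
    dict(plant_element=False, decoys=frozenset({"other_family", "scattered_cores", "cross_contig"})),
)


def generate_cohort(
    config: SimulationConfig,
) -> list[tuple[AnnotatedGenome, GenomeTruth]]:
    """Generate ``n_genomes`` genomes cycling through a schedule of true
    elements and decoy-only negatives; the host *fis* anchor is shared."""
    rng = np.random.default_rng([config.seed % (2**31), 7_777])
    fis_seq = random_orf(rng, _ROLE_NT["fis"])
    out = []
    for i in range(config.n_genomes):
        variant = _COHORT_SCHEDULE[i % len(_COHORT_SCHEDULE)]
        strand = "+" if (i // len(_COHORT_SCHEDULE)) % 2 == 0 else "-"
        cfg = replace(config, element_strand=strand, **variant)
        out.append(generate_genome(cfg, i, fis_seq=fis_seq))
    return out


def mutate_element(
    element_seq: str,
    divergence: float,
    seed: int | np.random.Generator,
    *,
    indel_fraction: float = 0.10,
) -> str:
    """Mutate a sequence to an expected per-base divergence.

    ``indel_fraction`` of mutation events are 1-3 bp indels, the rest
    substitutions to a different base.
    """
    if not (0 <= divergence <= 0.5):
        raise ValueError("divergence must be in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = list(element_seq)
    hit = np.flatnonzero(rng.random(len(seq)) < divergence)
    for pos in hit[::-1]:  # right-to-left so indels do not shift later positions
        if rng.random() < indel_fraction:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                seq[pos : pos + size] = []
            else:
                seq[pos:pos] = list(random_dna(rng, size))
        else:
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)


def simulate_subfamily_elements(
    config: SimulationConfig,
    members_per_subfamily: int = 2,
) -> tuple[dict[str, str], dict[str, int]]:
    """Element sequences for ``n_subfamilies`` planted subfamilies.

    Each subfamily prototype diverges from a common ancestor by
    ``between_subfamily_divergence``; each member diverges from its prototype
    by ``within_subfamily_divergence``. Returns (id -> sequence,
    id -> subfamily label).
    """
    rng = np.random.default_rng([config.seed % (2**31), 31_337])
    ancestor = random_dna(rng, config.element_len)
    seqs: dict[str, str] = {}
    labels: dict[str, int] = {}
    for k in range(config.n_subfamilies):
        proto = mutate_element(ancestor, config.between_subfamily_divergence, rng)
        for m in range(members_per_subfamily):
            eid = f"sf{k}_m{m}"
            seqs[eid] = mutate_element(proto, config.within_subfamily_divergence, rng)
            labels[eid] = k
    return seqs, labels


@dataclass
class ReadSimResult:
    counts: PackagingCounts
    origins: np.ndarray  # per-read: 0 helper, 1 satellite, 2 chimera
    short_reads: Optional[list[tuple[str, str]]]
    long_phases: np.ndarray
    long_reads: Optional[list[tuple[str, str]]]
    helper_ref: Optional[str]
    satellite_unit: Optional[str]


def simulate_reads(
    config: SimulationConfig,
    *,
    mode: str = "pac",
    n_long_reads: int = 200,
    emit_sequences: bool = False,
    satellite_unit: Optional[str] = None,
) -> ReadSimResult:
    """Simulate short reads from a helper/satellite particle mixture and long
    reads from the satellite concatemer.

    Particles carry the satellite concatemer with probability
    ``hitchhiker_fraction``; short reads land on a particle's DNA uniformly,
    so the satellite read share is f*c*Ls / (f*c*Ls + (1-f)*Lh). Chimeric
    (hybrid) reads occur at ``chimera_rate``. Long-read start phases are
    uniform over the unit in ``pac`` mode and fixed at 0 in ``cos`` mode.
    """
    if mode not in {"pac", "cos"}:
        raise ValueError("mode must be 'pac' or 'cos'")
    rng = np.random.default_rng([config.seed % (2**31), 424_242])
    f = config.hitchhiker_fraction
    c = config.concatemer_copies
    ls, lh = config.element_len, config.helper_len
    p_sat = f * c * ls / (f * c * ls + (1 - f) * lh) if f > 0 else 0.0

    u = rng.random(config.n_reads)
    origins = np.where(u < p_sat, 1, 0).astype(np.int8)
    chim = rng.random(config.n_reads) < config.chimera_rate
    origins[chim] = 2
    counts = PackagingCounts(
        reads_helper=int(np.sum(origins == 0)),
        reads_satellite=int(np.sum(origins == 1)),
        reads_hybrid=int(np.sum(origins == 2)),
        len_helper=lh,
        len_satellite=ls,
        concatemer_copies=c,
    )

    helper_ref = sat_unit = None
    short_reads = None
    if emit_sequences:
        helper_ref = random_dna(rng, lh)
        sat_unit = satellite_unit or random_dna(rng, ls)
        concat = sat_unit * max(2, c)
        short_reads = []
        rl = config.read_len
        for i, origin in enumerate(origins):
            if origin == 0:
                s = int(rng.integers(0, lh - rl))
                short_reads.append((f"r{i}", helper_ref[s : s + rl]))
            elif origin == 1:
                s = int(rng.integers(0, len(concat) - rl))
                short_reads.append((f"r{i}", concat[s : s + rl]))
            else:
                s1 = int(rng.integers(0, lh - rl // 2))
                s2 = int(rng.integers(0, len(concat) - rl // 2))
                short_reads.append(
                    (f"r{i}", helper_ref[s1 : s1 + rl // 2] + concat[s2 : s2 + rl // 2])
                )

    if mode == "pac":
        phases = rng.integers(0, ls, size=n_long_reads).astype(float)
    else:
        phases = np.zeros(n_long_reads)
    long_reads = None
    if emit_sequences:
        sat_unit = sat_unit or (satellite_unit or random_dna(rng, ls))
        long_reads = []
        big = sat_unit * (c + 3)
        for i, ph in enumerate(phases):
            length = int(
                np.clip(rng.normal(config.long_read_len_mean, config.long_read_len_mean * 0.1),
                        ls // 2, c * ls)
            )
            start = int(ph)
            long_reads.append((f"lr{i}", big[start : start + length]))
    return ReadSimResult(
        counts=counts,
        origins=origins,
        short_reads=short_reads,
        long_phases=phases,
        long_reads=long_reads,
        helper_ref=helper_ref,
        satellite_unit=sat_unit,
    )
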