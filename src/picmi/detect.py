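"""PICMI detection: co-localization scan, exclusion filters, boundary
extraction via direct repeats, and small-ORF scanning.

The detection model mirrors how minimalist phage satellites are recognized:
three mandatory co-localized genes (an integrase, the AlpA-like regulator and
a primase, each identified by domain labels) anchored at the host *fis* gene,
with candidate loci then filtered against other satellite families (PICI,
cf-PICI, P4, PLE hallmark genes), cross-contig artefacts, decoy integration
anchors and oversized spans. Element boundaries are resolved from the pair of
exact direct repeats created by site-specific integration downstream of *fis*.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from ._align import global_protein_identity
from .genome import AnnotatedGenome, Contig, GeneFeature, normalize_domain_label

logger = logging.getLogger(__name__)

MANDATORY_ROLES = ("int", "alpA", "prim")


@dataclass
class DetectionModel:
    """Rule set defining a PICMI-like locus.

    Domain defaults are the Pfam families of the four marker genes: the
    tyrosine/serine integrase, AlpA, the DUF3987/DUF5906 primase and the Fis
    regulator. ``fis_policy`` controls whether the *fis* anchor is itself
    required in the window; ``max_gene_gap`` is the maximum number of
    intervening genes between consecutive core components.
    """

    integrase_domains: frozenset[str] = frozenset({"PF00589", "PF00239", "PF07508"})
    alpa_domains: frozenset[str] = frozenset({"PF05930", "PF12728"})
    primase_domains: frozenset[str] = frozenset({"PF13148", "PF19263"})
    fis_domains: frozenset[str] = frozenset({"PF02954"})
    fis_policy: str = "mandatory"
    max_gene_gap: int = 5
    max_element_len: int = 50_000
    other_family_hallmarks: frozenset[str] = frozenset({"terS", "sid", "ppi", "psu"})
    min_repeat_len: int = 15

    def __post_init__(self) -> None:
        for name in ("integrase_domains", "alpa_domains", "primase_domains", "fis_domains"):
            labels = getattr(self, name)
            if not labels:
                raise ValueError(f"{name} must be non-empty")
            setattr(self, name, frozenset(normalize_domain_label(x) for x in labels))
        if self.fis_policy not in {"mandatory", "optional"}:
            raise ValueError("fis_policy must be 'mandatory' or 'optional'")
        if self.max_gene_gap < 0:
            raise ValueError("max_gene_gap must be >= 0")
        if self.max_element_len <= 0:
            raise ValueError("max_element_len must be > 0")
        if self.min_repeat_len < 8:
            raise ValueError("min_repeat_len must be >= 8")
        self.other_family_hallmarks = frozenset(
            x.lower() for x in self.other_family_hallmarks
        )

    def roles_of(self, feature: GeneFeature) -> set[str]:
        """Core roles a feature can fill, by domain-label intersection."""
        roles = set()
        if feature.domain_labels & self.integrase_domains:
            roles.add("int")
        if feature.domain_labels & self.alpa_domains:
            roles.add("alpA")
        if feature.domain_labels & self.primase_domains:
            roles.add("prim")
        if feature.domain_labels & self.fis_domains:
            roles.add("fis")
        return roles

    @property
    def required_roles(self) -> tuple[str, ...]:
        if self.fis_policy == "mandatory":
            return MANDATORY_ROLES + ("fis",)
        return MANDATORY_ROLES


@dataclass
class PicmiCandidate:
    """A co-localized set of core-gene hits, before or after filtering."""

    genome_id: str
    contig_id: str
    core_hits: dict[str, GeneFeature]
    span: tuple[int, int]
    intervening_features: list[GeneFeature] = field(default_factory=list)
    filter_flags: set[str] = field(default_factory=set)
    rank: int = 0

    @property
    def span_len(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def retained(self) -> bool:
        return not self.filter_flags


@dataclass(frozen=True)
class DirectRepeat:
    """An exact repeat pair delimiting an integrated element (attL/attR)."""

    seq: str
    left_pos: int
    right_pos: int

    def __post_init__(self) -> None:
        if self.left_pos >= self.right_pos:
            raise ValueError("left_pos must be < right_pos")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class PicmiElement:
    """An extracted element: boundaries, oriented sequence and internal genes."""

    candidate: PicmiCandidate
    repeat: Optional[DirectRepeat]
    element_start: int
    element_end: int
    element_seq: str
    orientation: str  # fis_forward | fis_reverse (strand of fis on the contig)
    internal: list[GeneFeature] = field(default_factory=list)
    role_features: dict[str, GeneFeature] = field(default_factory=dict)
    small_orfs: list[GeneFeature] = field(default_factory=list)

    @property
    def element_id(self) -> str:
        return (
            f"{self.candidate.genome_id}|{self.candidate.contig_id}"
            f"|{self.element_start}-{self.element_end}"
        )

    def internal_features(self) -> list[GeneFeature]:
        return list(self.internal) + list(self.small_orfs)

    def __len__(self) -> int:
        return len(self.element_seq)


def _clusters(hit_indices: Sequence[int], max_gap: int) -> list[list[int]]:
    """Group sorted hit indices so consecutive hits have <= max_gap genes between."""
    groups: list[list[int]] = []
    for i in sorted(hit_indices):
        if groups and i - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def _chain_valid(indices: Sequence[int], max_gap: int) -> bool:
    idx = sorted(indices)
    return all(b - a - 1 <= max_gap for a, b in zip(idx, idx[1:]))


def _best_assignment(
    role_hits: dict[str, list[int]],
    roles: Sequence[str],
    feats: Sequence[GeneFeature],
    max_gap: int,
) -> Optional[dict[str, int]]:
    """Pick one hit per role minimizing the bp span, subject to the gap rule.

    A feature may match several role domains; assignments must be injective.
    """
    best = None
    best_key = None
    pools = [role_hits.get(r, []) for r in roles]
    if any(not p for p in pools):
        return None
    for combo in itertools.product(*pools):
        if len(set(combo)) != len(combo):
            continue
        if not _chain_valid(combo, max_gap):
            continue
        start = min(feats[i].start for i in combo)
        end = max(feats[i].end for i in combo)
        key = (end - start, start, combo)
        if best_key is None or key < best_key:
            best_key = key
            best = dict(zip(roles, combo))
    return best


def scan_genome(genome: AnnotatedGenome, model: DetectionModel) -> list[PicmiCandidate]:
    """Find every maximal co-localized core-gene locus.

    Hits of the mandatory roles (plus *fis* under the mandatory policy) are
    clustered per contig with at most ``max_gene_gap`` intervening genes
    between consecutive hits, order-agnostic and strand-agnostic; overlapping
    windows therefore merge. Within a cluster the reported role assignment is
    the closest-packed one (smallest bp span). Under the optional *fis*
    policy a co-localized *fis* hit is attached when one fits the gap rule.

    Genomes whose mandatory roles only co-occur across contigs yield a merged
    candidate spanning the contig that carries most roles; such candidates are
    flagged ``cross_contig`` by :func:`filter_candidates`.
    """
    candidates: list[PicmiCandidate] = []
    partials: list[tuple[str, dict[str, int], list[GeneFeature]]] = []

    for contig in genome.contigs:
        feats = genome.features_on(contig.id)
        role_hits: dict[str, list[int]] = {}
        hit_idx: set[int] = set()
        for i, f in enumerate(feats):
            for role in model.roles_of(f):
                role_hits.setdefault(role, []).append(i)
                hit_idx.add(i)
        for cluster in _clusters(sorted(hit_idx), model.max_gene_gap):
            cluster_set = set(cluster)
            local = {
                r: [i for i in idxs if i in cluster_set]
                for r, idxs in role_hits.items()
            }
            local = {r: v for r, v in local.items() if v}
            assignment = _best_assignment(
                local, model.required_roles, feats, model.max_gene_gap
            )
            if assignment is None:
                if set(local) & set(MANDATORY_ROLES):
                    partials.append((contig.id, local, feats))
                continue
            if model.fis_policy == "optional" and "fis" not in assignment and "fis" in local:
                with_fis = _best_assignment(
                    local, MANDATORY_ROLES + ("fis",), feats, model.max_gene_gap
                )
                if with_fis is not None:
                    assignment = with_fis
            candidates.append(
                _make_candidate(genome.genome_id, contig.id, assignment, feats)
            )

    candidates.extend(_merge_cross_contig(genome, model, partials))
    candidates.sort(key=lambda c: (c.span_len, c.contig_id, c.span[0]))
    for rank, c in enumerate(candidates):
        c.rank = rank
    return candidates


def _make_candidate(
    genome_id: str,
    contig_id: str,
    assignment: dict[str, int],
    feats: Sequence[GeneFeature],
) -> PicmiCandidate:
    core = {role: feats[i] for role, i in assignment.items()}
    start = min(f.start for f in core.values())
    end = max(f.end for f in core.values())
    chosen = set(assignment.values())
    intervening = [
        f
        for i, f in enumerate(feats)
        if i not in chosen and f.overlap(start, end) > 0
    ]
    return PicmiCandidate(
        genome_id=genome_id,
        contig_id=contig_id,
        core_hits=core,
        span=(start, end),
        intervening_features=intervening,
    )


def _merge_cross_contig(genome, model, partials) -> list[PicmiCandidate]:
    """Pair partial clusters on different contigs that jointly cover the model."""
    merged = []
    required = set(model.required_roles)
    for (c1, l1, f1), (c2, l2, f2) in itertools.combinations(partials, 2):
        if c1 == c2:
            continue
        if not required <= (set(l1) | set(l2)):
            continue
        # primary contig: the one carrying more mandatory roles
        if len(set(l2) & set(MANDATORY_ROLES)) > len(set(l1) & set(MANDATORY_ROLES)):
            (c1, l1, f1), (c2, l2, f2) = (c2, l2, f2), (c1, l1, f1)
        assignment1 = {
            r: l1[r][0] for r in required if r in l1
        }
        core = {r: f1[i] for r, i in assignment1.items()}
        for r in required - set(core):
            core[r] = f2[l2[r][0]]
        own = [f1[i] for i in assignment1.values()]
        start = min(f.start for f in own)
        end = max(f.end for f in own)
        cand = PicmiCandidate(
            genome_id=genome.genome_id,
            contig_id=c1,
            core_hits=core,
            span=(start, end),
            intervening_features=[
                f for f in f1 if f.overlap(start, end) > 0 and f not in own
            ],
        )
        merged.append(cand)
    return merged


def feature_protein(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Protein sequence of a gene: annotated translation, else translated CDS."""
    if feature.protein_seq:
        return feature.protein_seq
    nt = genome.contig(feature.contig_id).seq[feature.start : feature.end]
    if feature.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    return aa.rstrip("*")


def filter_candidates(
    candidates: Sequence[PicmiCandidate],
    genome: AnnotatedGenome,
    model: DetectionModel,
    fis_reference: str,
    decoy_anchors: Optional[Sequence[str]] = None,
) -> tuple[list[PicmiCandidate], list[PicmiCandidate]]:
    """Apply the exclusion filters; returns (retained, flagged).

    Flags: ``cross_contig`` when int/alpA/fis hits sit on different contigs;
    ``other_family`` when the span contains a gene with a hallmark label of
    another satellite family (terS/sid/ppi/psu); ``bad_fis_anchor`` when the
    anchor's protein identity to the supplied Fis reference is below 30% or
    below its identity to any decoy anchor; ``oversize`` when the span
    exceeds ``max_element_len``.
    """
    if not fis_reference:
        raise ValueError("fis_reference protein sequence must be non-empty")
    retained: list[PicmiCandidate] = []
    flagged: list[PicmiCandidate] = []
    for cand in candidates:
        flags: set[str] = set()
        anchor_contigs = {
            f.contig_id
            for role, f in cand.core_hits.items()
            if role in {"int", "alpA", "fis"}
        }
        if len(anchor_contigs) > 1:
            flags.add("cross_contig")
        span_feats = list(cand.intervening_features) + list(cand.core_hits.values())
        for f in span_feats:
            if f.product_label and f.product_label.lower() in model.other_family_hallmarks:
                flags.add("other_family")
                break
        anchor = cand.core_hits.get("fis")
        if anchor is not None:
            ident = global_protein_identity(
                feature_protein(genome, anchor), fis_reference
            )
            if ident < 0.30:
                flags.add("bad_fis_anchor")
            elif decoy_anchors:
                for decoy in decoy_anchors:
                    if global_protein_identity(feature_protein(genome, anchor), decoy) > ident:
                        flags.add("bad_fis_anchor")
                        break
        if cand.span_len > model.max_element_len:
            flags.add("oversize")
        cand.filter_flags = flags
        (retained if not flags else flagged).append(cand)
    if len(retained) > 1:
        # the family is characterized by at most one element per genome
        warnings.warn(
            f"{genome.genome_id}: {len(retained)} retained candidates; "
            "ranking keeps all, smallest span first",
            stacklevel=2,
        )
    return retained, flagged


def find_direct_repeats(
    contig: Contig,
    anchor_region: tuple[int, int],
    search_region: tuple[int, int],
    min_len: int = 15,
) -> Optional[DirectRepeat]:
    """Longest exact repeat with one copy in each region.

    Ties break by the pair spanning the largest interval, then leftmost.
    Returns None when no shared substring reaches ``min_len``.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    for name, (lo, hi) in (("anchor", anchor_region), ("search", search_region)):
        if lo >= hi:
            raise ValueError(f"{name}_region is inverted or empty: {(lo, hi)}")
        if lo < 0 or hi > contig.length:
            raise ValueError(f"{name}_region outside contig bounds")
    a0, a1 = anchor_region
    s0, s1 = search_region
    a, s = contig.seq[a0:a1], contig.seq[s0:s1]

    def pairs_at(k: int) -> list[tuple[int, int]]:
        if k > min(len(a), len(s)):
            return []
        kmers: dict[str, list[int]] = {}
        for i in range(len(a) - k + 1):
            kmers.setdefault(a[i : i + k], []).append(a0 + i)
        out = []
        for j in range(len(s) - k + 1):
            for pa in kmers.get(s[j : j + k], ()):
                ps = s0 + j
                if pa != ps:
                    out.append((min(pa, ps), max(pa, ps)))
        return out

    # longest shared substring length is monotone: binary search on k
    lo_k, hi_k = min_len, min(len(a), len(s))
    if not pairs_at(lo_k):
        return None
    while lo_k < hi_k:
        mid = (lo_k + hi_k + 1) // 2
        if pairs_at(mid):
            lo_k = mid
        else:
            hi_k = mid - 1
    best = pairs_at(lo_k)
    left, right = max(best, key=lambda p: (p[1] - p[0], -p[0], -p[1]))
    return DirectRepeat(seq=contig.seq[left : left + lo_k], left_pos=left, right_pos=right)


def _to_element_coords(
    f: GeneFeature, element_start: int, element_end: int, orientation: str, element_id: str
) -> Optional[GeneFeature]:
    if f.overlap(element_start, element_end) <= 0:
        return None
    start = max(f.start, element_start)
    end = min(f.end, element_end)
    if orientation == "fis_forward":
        new = (start - element_start, end - element_start, f.strand)
    else:
        flipped = "-" if f.strand == "+" else "+"
        new = (element_end - end, element_end - start, flipped)
    return GeneFeature(
        gene_id=f.gene_id,
        contig_id=element_id,
        start=new[0],
        end=new[1],
        strand=new[2],
        domain_labels=f.domain_labels,
        product_label=f.product_label,
        protein_seq=f.protein_seq,
    )


def extract_element(
    genome: AnnotatedGenome,
    candidate: PicmiCandidate,
    repeat: Optional[DirectRepeat],
    *,
    model: Optional[DetectionModel] = None,
    fallback_margin: int = 1000,
) -> PicmiElement:
    """Extract the element from the first base of *fis* to the far edge of the
    boundary repeat on the int-distal side.

    The sequence is reported in fis-forward orientation (reverse-complemented
    when *fis* lies on the minus strand). Without a repeat the element falls
    back to ``[fis start, int end + fallback_margin]`` and ``repeat`` stays
    None.
    """
    model = model or DetectionModel()
    contig = genome.contig(candidate.contig_id)
    fis = candidate.core_hits.get("fis")
    intg = candidate.core_hits["int"]
    forward = fis is None or fis.strand == "+"

    if forward:
        start = fis.start if fis is not None else candidate.span[0]
        if repeat is not None:
            end = repeat.right_pos + repeat.length
        else:
            end = min(contig.length, intg.end + fallback_margin)
        orientation = "fis_forward"
    else:
        end = fis.end
        if repeat is not None:
            start = repeat.left_pos
        else:
            start = max(0, intg.start - fallback_margin)
        orientation = "fis_reverse"

    if end - start > model.max_element_len:
        raise ValueError(
            f"oversize: element [{start}, {end}) exceeds {model.max_element_len} bp"
        )
    seq = contig.seq[start:end]
    if orientation == "fis_reverse":
        seq = str(Seq(seq).reverse_complement())

    eid = f"{candidate.genome_id}|{candidate.contig_id}|{start}-{end}"
    internal = []
    roles: dict[str, GeneFeature] = {}
    span_feats = {f.gene_id: f for f in candidate.intervening_features}
    for role, f in candidate.core_hits.items():
        span_feats[f.gene_id] = f
    for f in genome.features_on(candidate.contig_id):
        if f.gene_id not in span_feats and f.overlap(start, end) > 0:
            span_feats[f.gene_id] = f
    role_by_gene = {f.gene_id: r for r, f in candidate.core_hits.items()}
    for f in sorted(span_feats.values(), key=lambda x: x.start):
        conv = _to_element_coords(f, start, end, orientation, eid)
        if conv is None:
            continue
        internal.append(conv)
        if f.gene_id in role_by_gene:
            roles[role_by_gene[f.gene_id]] = conv
    internal.sort(key=lambda x: x.start)
    return PicmiElement(
        candidate=candidate,
        repeat=repeat,
        element_start=start,
        element_end=end,
        element_seq=seq,
        orientation=orientation,
        internal=internal,
        role_features=roles,
    )


_STOPS = {"TAA", "TAG", "TGA"}


def find_small_orfs(
    element: PicmiElement, min_aa: int = 30, max_aa: int = 60
) -> list[GeneFeature]:
    """Six-frame scan for small ATG-initiated ORFs in non-coding stretches.

    Reports every ATG..stop pair with ``min_aa <= aa_length < max_aa`` whose
    overlap with annotated genes is at most 30 bp; coordinates are on the
    fis-forward element. ``aa_length`` excludes the stop codon.
    """
    seq = element.element_seq
    n = len(seq)
    genes = [(f.start, f.end) for f in element.internal]
    found: list[GeneFeature] = []

    def coding_overlap(start: int, end: int) -> int:
        return sum(max(0, min(end, ge) - max(start, gs)) for gs, ge in genes)

    def scan(s: str, strand: str) -> None:
        for frame in range(3):
            starts: list[int] = []
            for pos in range(frame, len(s) - 2, 3):
                codon = s[pos : pos + 3]
                if codon == "ATG":
                    starts.append(pos)
                elif codon in _STOPS:
                    for atg in starts:
                        aa_len = (pos - atg) // 3
                        if min_aa <= aa_len < max_aa:
                            lo, hi = atg, pos + 3
                            if strand == "-":
                                lo, hi = n - hi, n - atg
                            if coding_overlap(lo, hi) <= 30:
                                prot = str(Seq(s[atg:pos]).translate())
                                found.append(
                                    GeneFeature(
                                        gene_id=f"{element.element_id}_sorf{len(found)}",
                                        contig_id=element.element_id,
                                        start=lo,
                                        end=hi,
                                        strand=strand,
                                        product_label="small_orf",
                                        protein_seq=prot,
                                    )
                                )
                    starts = []

    scan(seq, "+")
    scan(str(Seq(seq).reverse_complement()), "-")
    found.sort(key=lambda f: (f.start, f.end, f.strand))
    for i, f in enumerate(found):
        f.gene_id = f"{element.element_id}_sorf{i}"
    return found


def detect_elements(
    genome: AnnotatedGenome,
    model: Optional[DetectionModel] = None,
    fis_reference: Optional[str] = None,
    decoy_anchors: Optional[Sequence[str]] = None,
    *,
    repeat_margin: int = 600,
    fallback_margin: int = 1000,
    scan_small_orfs: bool = True,
) -> tuple[list[PicmiElement], list[PicmiCandidate]]:
    """Full per-genome pipeline: scan, filter, locate repeats, extract.

    When ``fis_reference`` is None the genome's own anchor protein is used,
    which disables the identity filter but keeps the others. Returns the
    extracted elements (smallest span first) and all candidates with their
    filter flags for reporting.
    """
    model = model or DetectionModel()
    candidates = scan_genome(genome, model)
    if not candidates:
        return [], []
    ref = fis_reference
    if ref is None:
        for cand in candidates:
            if "fis" in cand.core_hits:
                ref = feature_protein(genome, cand.core_hits["fis"])
                break
    if ref is None:
        retained = [c for c in candidates if not c.filter_flags]
        flagged = []
    else:
        retained, flagged = filter_candidates(
            candidates, genome, model, ref, decoy_anchors
        )
    elements = []
    for cand in retained:
        contig = genome.contig(cand.contig_id)
        fis = cand.core_hits.get("fis")
        intg = cand.core_hits["int"]
        repeat = None
        if fis is not None:
            if fis.strand == "+":
                anchor = (max(0, fis.end - 20), min(contig.length, fis.end + repeat_margin))
                search = (intg.end, min(contig.length, intg.end + repeat_margin))
            else:
                anchor = (max(0, fis.start - repeat_margin), min(contig.length, fis.start + 20))
                search = (max(0, intg.start - repeat_margin), intg.start)
            if anchor[0] < anchor[1] and search[0] < search[1]:
                repeat = find_direct_repeats(
                    contig, anchor, search, min_len=model.min_repeat_len
                )
        try:
            element = extract_element(
                genome, cand, repeat, model=model, fallback_margin=fallback_margin
            )
        except ValueError:
            cand.filter_flags.add("oversize")
            flagged.append(cand)
            continue
        if scan_small_orfs:
            element.small_orfs = find_small_orfs(element)
        elements.append(element)
    return elements, candidates
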