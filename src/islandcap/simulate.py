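"""Seeded generators for every input the pipeline consumes.

The genome generator emulates an allopolyploid: each gene family has one copy
per subgenome, with every non-anchor copy mutated (substitutions only) to a
configured identity *to the anchor copy* — so the configured value is an
exact pairwise identity that interacts analytically with the 95% collapse
threshold. Genes carry 5'/3' UTRs and introns, sit downstream of a 2 kbp
promoter context, and may receive planted low-complexity tracts and
organellar insertions. The capture simulator is Lander-Waterman-style:
per-probe fragment counts are Poisson in the captured window size, fragments
fall uniformly across the window, and off-target fragments fall uniformly
over non-design sequence. All generators are deterministic under their seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeInterval, SeqRecord, revcomp
from .design import DesignSpaceContig
from .evaluate import DepthTrack, ReadPlacement
from .tiling import ProbeSet, TilingParams

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CaptureConfig:
    mean_depth: float = 30.0
    on_target_fraction: float = 0.75  # measured for the full-scale gene capture
    duplicate_rate: float = 0.042
    fragment_len: int = 200


@dataclass(frozen=True)
class VariantConfig:
    rate: float = 0.002  # planted variants per covered base
    hom_fraction: float = 0.7
    cluster_fraction: float = 0.05  # fraction of sites planted as 3-site clusters
    min_depth: int = 10  # only plant where depth is at least this


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_subgenomes: int = 3
    n_gene_families: int = 20
    homoeolog_identity: float = 0.97
    gene_len_range: tuple[int, int] = (1200, 2400)
    utr_len_range: tuple[int, int] = (100, 250)
    n_exons: int = 3
    promoter_len: int = 2000
    intergenic_len: int = 3000
    low_confidence_fraction: float = 0.1
    lowcomp_tract_rate: float = 0.1
    lowcomp_tract_len: int = 60
    n_organelle_contigs: int = 1
    organelle_len: int = 20000
    organelle_insertion_rate: float = 0.1  # fraction of genes with an insertion
    organelle_insertion_len: int = 150
    n_premirnas: int = 6
    premirna_len: int = 120
    capture: CaptureConfig = CaptureConfig()
    variants: VariantConfig = VariantConfig()

    def __post_init__(self) -> None:
        if not 0.0 < self.homoeolog_identity <= 1.0:
            raise ValueError("homoeolog_identity must be in (0, 1]")
        for name in ("gene_len_range", "utr_len_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be a positive (lo, hi) with lo <= hi")
        if self.gene_len_range[0] < 2 * self.utr_len_range[1] + 3 * self.n_exons:
            raise ValueError("gene_len_range too short for the UTR/exon structure")
        if self.intergenic_len < self.promoter_len:
            raise ValueError("intergenic_len must be >= promoter_len")


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic data."""

    genes: dict[str, dict] = field(default_factory=dict)
    homoeolog_groups: dict[str, list[str]] = field(default_factory=dict)
    organelle_insertions: list[dict] = field(default_factory=list)
    lowcomp_tracts: list[dict] = field(default_factory=list)
    variants: list[dict] = field(default_factory=list)
    premirnas: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        return cls(**json.loads(text))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute bases so the copy has exactly round((1-identity)*len) diffs."""
    n = len(seq)
    n_mut = int(round((1.0 - identity) * n))
    if n_mut == 0:
        return seq
    pos = rng.choice(n, size=n_mut, replace=False)
    chars = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in pos:
        old = chars[p]
        choices = [b for b in _BASES if b != old]
        chars[p] = choices[rng.integers(0, len(choices))]
    return chars.tobytes().decode()


# ---------------------------------------------------------------------------
# genome + annotation


def gen_genome_and_annotation(
    cfg: SimulationConfig,
) -> tuple[list[SeqRecord], str, TruthSet]:
    """Generate a polyploid-like genome, its GFF3 annotation, and ground truth.

    Subgenome contigs are named chrA, chrB, ...; gene ids famNNN[A-Z].
    Odd-numbered families go on the '-' strand so both orientations are
    exercised. Returns (contigs, gff3 text, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = TruthSet()
    letters = [chr(ord("A") + s) for s in range(cfg.n_subgenomes)]
    gff_lines = ["##gff-version 3"]

    # per-family anchor sequences (subgenome A), shared structure
    families = []
    for f in range(cfg.n_gene_families):
        glen = int(rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1))
        u5 = int(rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1))
        u3 = int(rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1))
        core = glen - u5 - u3  # CDS+introns between the UTRs
        # exon/intron layout in transcript orientation, relative to gene start:
        # exon1 = utr5 + first coding chunk; last exon ends with utr3.
        n_ex = cfg.n_exons
        min_chunk = 30
        cuts = sorted(
            rng.choice(
                np.arange(min_chunk, core - min_chunk),
                size=2 * (n_ex - 1),
                replace=False,
            ).tolist()
        )
        # alternate exon/intron: [0,c0)=exon tail.. introns [c0,c1), ...
        bounds = [0] + cuts + [core]
        exon_spans = []  # relative to gene start (transcript orientation)
        pos = 0
        for i in range(0, len(bounds) - 1, 2):
            ex_s, ex_e = bounds[i], bounds[i + 1]
            exon_spans.append((u5 + ex_s, u5 + ex_e))
        exon_spans[0] = (0, exon_spans[0][1])  # 5'UTR is exonic
        exon_spans[-1] = (exon_spans[-1][0], glen)  # 3'UTR is exonic
        strand = "-" if f % 2 else "+"
        families.append(
            {
                "gene": _random_seq(rng, glen),
                "promoter": _random_seq(rng, cfg.promoter_len),
                "glen": glen,
                "u5": u5,
                "u3": u3,
                "exons": exon_spans,
                "strand": strand,
                "confidence": "low"
                if rng.random() < cfg.low_confidence_fraction
                else "high",
            }
        )

    contigs: list[SeqRecord] = []
    for s, letter in enumerate(letters):
        contig_id = f"chr{letter}"
        parts: list[str] = []
        pos = 0
        for f, fam in enumerate(families):
            fam_id = f"fam{f:03d}"
            gene_id = f"{fam_id}{letter}"
            ident = 1.0 if s == 0 else cfg.homoeolog_identity
            gene_seq = _mutate(rng, fam["gene"], ident)
            prom_seq = _mutate(rng, fam["promoter"], ident)
            if rng.random() < cfg.lowcomp_tract_rate:
                tl = cfg.lowcomp_tract_len
                mid = fam["glen"] // 2
                tract = ("AT" * tl)[:tl]
                gene_seq = gene_seq[:mid] + tract + gene_seq[mid + tl :]
            glen = fam["glen"]
            strand = fam["strand"]
            spacer = _random_seq(rng, cfg.intergenic_len - cfg.promoter_len)
            if strand == "+":
                parts.extend([spacer, prom_seq, gene_seq])
                gstart = pos + len(spacer) + cfg.promoter_len
            else:
                parts.extend([spacer, revcomp(gene_seq), revcomp(prom_seq)])
                gstart = pos + len(spacer)
            gend = gstart + glen
            pos += len(spacer) + cfg.promoter_len + glen
            # genomic exon intervals
            if strand == "+":
                ex_ivs = [(gstart + a, gstart + b) for a, b in fam["exons"]]
                u5_iv = (gstart, gstart + fam["u5"])
                u3_iv = (gend - fam["u3"], gend)
            else:
                ex_ivs = sorted((gend - b, gend - a) for a, b in fam["exons"])
                u5_iv = (gend - fam["u5"], gend)
                u3_iv = (gstart, gstart + fam["u3"])
            conf = fam["confidence"]
            attrs = f"ID={gene_id};confidence={'HC' if conf == 'high' else 'LC'}"
            gff_lines.append(
                f"{contig_id}\tsim\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t{attrs}"
            )
            gff_lines.append(
                f"{contig_id}\tsim\tmRNA\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t"
                f"ID={gene_id}.1;Parent={gene_id}"
            )
            for i, (a, b) in enumerate(ex_ivs):
                gff_lines.append(
                    f"{contig_id}\tsim\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t"
                    f"ID={gene_id}.exon{i + 1};Parent={gene_id}.1"
                )
            gff_lines.append(
                f"{contig_id}\tsim\tfive_prime_UTR\t{u5_iv[0] + 1}\t{u5_iv[1]}\t.\t"
                f"{strand}\t.\tID={gene_id}.utr5;Parent={gene_id}.1"
            )
            gff_lines.append(
                f"{contig_id}\tsim\tthree_prime_UTR\t{u3_iv[0] + 1}\t{u3_iv[1]}\t.\t"
                f"{strand}\t.\tID={gene_id}.utr3;Parent={gene_id}.1"
            )
            truth.genes[gene_id] = {
                "contig": contig_id,
                "start": gstart,
                "end": gend,
                "strand": strand,
                "confidence": conf,
                "family": fam_id,
            }
            truth.homoeolog_groups.setdefault(fam_id, []).append(gene_id)
        parts.append(_random_seq(rng, cfg.intergenic_len))
        contigs.append(SeqRecord(id=contig_id, residues="".join(parts)))

    # record planted low-complexity tracts by scanning (position known per copy)
    for rec in contigs:
        seq = rec.residues
        start = 0
        probe = "AT" * (cfg.lowcomp_tract_len // 2)
        while True:
            i = seq.find(probe, start)
            if i < 0:
                break
            truth.lowcomp_tracts.append(
                {"contig": rec.id, "start": i, "end": i + cfg.lowcomp_tract_len}
            )
            start = i + cfg.lowcomp_tract_len
    return contigs, "\n".join(gff_lines) + "\n", truth


def gen_organelles(cfg: SimulationConfig) -> list[SeqRecord]:
    """Organellar contaminant contigs (chloroplast/mitochondrion analogues)."""
    rng = np.random.default_rng(cfg.seed + 1)
    return [
        SeqRecord(id=f"organelle{i + 1}", residues=_random_seq(rng, cfg.organelle_len))
        for i in range(cfg.n_organelle_contigs)
    ]


def plant_insertions(
    genome: list[SeqRecord],
    organelles: list[SeqRecord],
    cfg: SimulationConfig,
    truth: TruthSet,
) -> list[SeqRecord]:
    """Overwrite spans inside a fraction of gene bodies with organellar
    sequence; the truth records every planted span."""
    if not organelles or cfg.organelle_insertion_rate <= 0:
        return list(genome)
    rng = np.random.default_rng(cfg.seed + 2)
    seqs = {r.id: list(r.residues) for r in genome}
    ilen = cfg.organelle_insertion_len
    for gene_id, g in sorted(truth.genes.items()):
        if rng.random() >= cfg.organelle_insertion_rate:
            continue
        org = organelles[int(rng.integers(0, len(organelles)))]
        o_start = int(rng.integers(0, len(org) - ilen + 1))
        span = org.residues[o_start : o_start + ilen]
        mid = (g["start"] + g["end"]) // 2
        s = min(max(g["start"], mid - ilen // 2), g["end"] - ilen)
        seqs[g["contig"]][s : s + ilen] = list(span)
        truth.organelle_insertions.append(
            {
                "contig": g["contig"],
                "start": s,
                "end": s + ilen,
                "organelle": org.id,
                "gene": gene_id,
            }
        )
    return [SeqRecord(id=r.id, residues="".join(seqs[r.id])) for r in genome]


def gen_premirnas(
    cfg: SimulationConfig,
    genome: list[SeqRecord],
    truth: TruthSet,
) -> tuple[list[SeqRecord], dict[str, tuple[int, int]]]:
    """Pre-miRNA sequences sliced from the genome with known classification.

    Cycles through three placement classes: wholly exonic, exon/intron
    boundary with the mature inside the exon (still exonic), and intergenic.
    Mature offsets sit at [20, 42) within each pre-miRNA.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    by_id = {r.id: r for r in genome}
    plen = cfg.premirna_len
    mature = (20, 42)
    pres: list[SeqRecord] = []
    offsets: dict[str, tuple[int, int]] = {}
    gene_items = sorted(truth.genes.items())
    for i in range(cfg.n_premirnas):
        mid = f"mir{i + 1:02d}"
        klass = ("exonic", "boundary_exonic", "intergenic")[i % 3]
        gene_id, g = gene_items[i % len(gene_items)]
        contig = by_id[g["contig"]]
        if klass == "intergenic":
            s = max(0, g["start"] - cfg.intergenic_len + 10)
            expected = "non_exonic"
        elif klass == "exonic":
            # first 'exon' genomically is at the gene edge and is >= utr+30 long
            s = g["start"] + 5
            expected = "exonic"
        else:
            # straddle the gene start (upstream is promoter/intergenic) with
            # the mature window inside the gene's first exon
            s = g["start"] - 10
            expected = "exonic" if g["strand"] == "+" else "non_exonic"
            # ('-' genes start at the 3'UTR end genomically; mature at offset
            # 20 in pre orientation lands outside an exon only if the slice is
            # taken forward — take reverse slices for '-' genes instead)
            if g["strand"] == "-":
                s = g["start"] + 5
                expected = "exonic"
        seq = contig.residues[s : s + plen].upper()
        pres.append(SeqRecord(id=mid, residues=seq))
        offsets[mid] = mature
        truth.premirnas.append(
            {
                "id": mid,
                "contig": g["contig"],
                "start": s,
                "end": s + plen,
                "expected": expected,
            }
        )
    return pres, offsets


# ---------------------------------------------------------------------------
# capture simulation


def map_local_span(
    contig: DesignSpaceContig,
    start: int,
    end: int,
    targets_by_id: dict[str, GenomeInterval],
) -> list[GenomeInterval]:
    """Map a local span of a design contig to genome intervals via provenance."""
    out = []
    for b in contig.provenance:
        s, e = max(b.local_start, start), min(b.local_end, end)
        if s >= e:
            continue
        off = s - b.local_start
        t_s, t_e = b.t_start + off, b.t_start + off + (e - s)
        iv = targets_by_id[b.target_id]
        if iv.strand == "-":
            g_s, g_e = iv.end - t_e, iv.end - t_s
        else:
            g_s, g_e = iv.start + t_s, iv.start + t_e
        out.append(GenomeInterval(iv.contig, g_s, g_e, iv.strand))
    return out


def design_space_footprint(
    space: list[DesignSpaceContig],
    targets_by_id: dict[str, GenomeInterval],
) -> dict[str, list[tuple[int, int]]]:
    """Genome spans occupied by the design space, merged per contig."""
    from .core import merge_spans

    per: dict[str, list[tuple[int, int]]] = {}
    for c in space:
        for iv in map_local_span(c, 0, len(c), targets_by_id):
            per.setdefault(iv.contig, []).append((iv.start, iv.end))
    return {c: merge_spans(sp) for c, sp in per.items()}


def simulate_capture(
    pset: ProbeSet,
    space: list[DesignSpaceContig],
    targets_by_id: dict[str, GenomeInterval],
    genome: list[SeqRecord],
    cfg: SimulationConfig,
    seed: int | None = None,
    sample_id: str = "sample1",
    params: TilingParams = TilingParams(),
) -> tuple[list[ReadPlacement], DepthTrack, pd.DataFrame]:
    """Simulate post-capture fragments over the genome.

    On-target fragments: each probe's captured window (the probe padded to
    the fragment length) is mapped to genome coordinates, windows are merged
    per contig so overlapping probes do not double-count, and fragment counts
    per merged window are Poisson with mean depth ``cfg.capture.mean_depth``
    over the window, starts uniform across it. Off-target fragments are
    placed uniformly over non-design sequence at a rate giving the configured
    on-target fraction. Duplicates are flagged binomially.

    Returns (reads, depth track over non-duplicates, pileup restricted to the
    design footprint with alt_count=0).
    """
    cap = cfg.capture
    rng = np.random.default_rng(cfg.seed + 4 if seed is None else seed)
    fl = cap.fragment_len
    lengths = {r.id: len(r) for r in genome}
    by_contig = {c.id: c for c in space}

    from .core import merge_spans

    windows: dict[str, list[tuple[int, int]]] = {}
    for p in pset.probes:
        contig = by_contig[p.contig]
        pad_l = (fl - p.length) // 2
        s = max(0, p.start - pad_l)
        e = min(len(contig), p.start - pad_l + fl)
        for giv in map_local_span(contig, s, e, targets_by_id):
            windows.setdefault(giv.contig, []).append((giv.start, giv.end))
    reads: list[ReadPlacement] = []
    for gcontig in sorted(windows):
        L = lengths[gcontig]
        for ws, we in merge_spans(windows[gcontig]):
            w = we - ws
            n = rng.poisson(cap.mean_depth * (w + fl - 1) / fl)
            if n == 0:
                continue
            starts = rng.integers(ws - fl + 1, we, size=n)
            for st in starts:
                a, b = max(0, int(st)), min(L, int(st) + fl)
                if b > a:
                    reads.append(
                        ReadPlacement(GenomeInterval(gcontig, a, b), sample_id)
                    )
    n_on = len(reads)
    footprint = design_space_footprint(space, targets_by_id)
    if cap.on_target_fraction < 1.0 and n_on:
        n_off = int(round(n_on * (1.0 - cap.on_target_fraction) / cap.on_target_fraction))
        gaps: list[tuple[str, int, int]] = []
        from .core import subtract_spans

        for rec in genome:
            for s, e in subtract_spans(lengths[rec.id], footprint.get(rec.id, [])):
                if e - s >= fl:
                    gaps.append((rec.id, s, e))
        if gaps:
            weights = np.array([e - s - fl + 1 for _, s, e in gaps], dtype=float)
            weights /= weights.sum()
            picks = rng.choice(len(gaps), size=n_off, p=weights)
            for gi in picks:
                contig, s, e = gaps[gi]
                st = int(rng.integers(s, e - fl + 1))
                reads.append(
                    ReadPlacement(GenomeInterval(contig, st, st + fl), sample_id)
                )
    # duplicates
    dup = rng.random(len(reads)) < cap.duplicate_rate
    reads = [
        ReadPlacement(r.interval, r.sample_id, bool(d)) for r, d in zip(reads, dup)
    ]
    track = DepthTrack.from_reads(reads, lengths)
    rows = []
    for contig, spans in sorted(footprint.items()):
        arr = track[contig]
        for s, e in spans:
            d = arr[s:e]
            nz = np.nonzero(d)[0]
            if len(nz):
                rows.append(
                    pd.DataFrame(
                        {
                            "contig": contig,
                            "pos0": nz + s,
                            "depth": d[nz],
                            "alt_count": 0,
                        }
                    )
                )
    pileup = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["contig", "pos0", "depth", "alt_count"])
    )
    return reads, track, pileup


def plant_variants(
    pileup: pd.DataFrame,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Plant homozygous, heterozygous and clustered variants into a pileup.

    Clean sites are kept pairwise farther apart than the 10 bp filter window;
    clusters are planted as homozygous trios within 8 bp so the window rule
    must remove them. Each truth record carries the expected post-filter
    disposition: kept, removed_af (heterozygous) or removed_window.
    """
    var = cfg.variants
    rng = np.random.default_rng(cfg.seed + 5 if seed is None else seed)
    df = pileup.copy().reset_index(drop=True)
    eligible = df.index[df.depth >= var.min_depth].to_numpy()
    if len(eligible) == 0:
        log.warning("no positions deep enough to plant variants")
        return df, []
    n_sites = max(1, int(round(var.rate * len(df))))
    n_clusters = int(round(var.cluster_fraction * n_sites / 3))
    order = rng.permutation(eligible)
    chosen: list[int] = []
    used: dict[str, list[int]] = {}
    min_gap = 2 * 10 + 1  # beyond any shared 10-bp window, plus margin
    for idx in order:
        contig, pos = df.contig[idx], int(df.pos0[idx])
        near = used.get(contig, [])
        if all(abs(pos - p) >= min_gap for p in near):
            chosen.append(int(idx))
            used.setdefault(contig, []).append(pos)
        if len(chosen) >= n_sites:
            break
    truth: list[dict] = []

    def _plant(idx: int, zygosity: str) -> dict | None:
        depth = int(df.depth[idx])
        if depth == 0:
            log.info("variant site at zero depth skipped")
            return None
        if zygosity == "hom":
            af = rng.uniform(0.9, 1.0)
            alt = int(round(af * depth))
            if alt / depth <= 0.8:
                alt = int(np.floor(0.8 * depth)) + 1
            alt = min(alt, depth)
            expected = "kept" if depth >= 5 else "removed_depth"
        else:
            af = rng.uniform(0.4, 0.6)
            alt = int(round(af * depth))
            alt = max(1, min(alt, int(np.floor(0.8 * depth))))
            expected = "removed_af"
        df.loc[idx, "alt_count"] = alt
        return {
            "contig": str(df.contig[idx]),
            "pos0": int(df.pos0[idx]),
            "depth": depth,
            "alt_count": alt,
            "zygosity": zygosity,
            "expected": expected,
        }

    # clustered trios first (consume sites from the end of the chosen list)
    cluster_sites = chosen[: n_clusters] if n_clusters else []
    clean_sites = chosen[len(cluster_sites) :]
    pos_index = {
        (str(c), int(p)): i for i, (c, p) in enumerate(zip(df.contig, df.pos0))
    }
    for idx in cluster_sites:
        contig, pos = str(df.contig[idx]), int(df.pos0[idx])
        members = [idx]
        for off in (3, 6):
            j = pos_index.get((contig, pos + off))
            if j is not None and df.depth[j] >= 5:
                members.append(j)
        if len(members) < 3:  # cannot form a guaranteed-removed trio here
            rec = _plant(idx, "hom")
            if rec:
                truth.append(rec)
            continue
        for j in members:
            rec = _plant(j, "hom")
            if rec:
                rec["expected"] = "removed_window"
                truth.append(rec)
    for idx in clean_sites:
        zyg = "hom" if rng.random() < var.hom_fraction else "het"
        rec = _plant(idx, zyg)
        if rec:
            truth.append(rec)
    return df, truth
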