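"""Variant and CNV handling for the association stage.

Loads biallelic SNP/indel genotypes, restricts them to core-genome regions
with a minor-allele-frequency filter, chains markers into LD blocks, builds
the genomic relationship (kinship) matrix for the mixed model, derives
binary CNV presence markers from the overlap structure of per-strain CNV
segments, and assigns CNV events to genes.

All internal coordinates are 0-based half-open; VCF positions are converted
on read, BED coordinates are native.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "CoreMask",
    "LDBlock",
    "CNVMarker",
    "KinshipMatrix",
    "read_vcf",
    "write_vcf",
    "read_bed_mask",
    "read_genes",
    "filter_core_maf",
    "ld_blocks",
    "kinship",
    "classify_cnv",
    "cnv_markers",
    "gene_cnv_events",
]

MARKER_COLUMNS = ("chrom", "pos", "ref", "alt", "kind")


@dataclass
class GenotypeMatrix:
    """Biallelic markers x strains dosage matrix.

    ``markers``: DataFrame with chrom, pos (0-based), ref, alt, kind
    (snp|indel).  ``dosages``: float array (n_markers x n_strains) with
    values {0, 1, 2} and NaN for missing calls.
    """

    markers: pd.DataFrame
    dosages: np.ndarray
    strains: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.markers), len(self.strains)):
            raise ValueError("dosage shape must be (n_markers, n_strains)")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency, in [0, 0.5]."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(self.dosages, axis=1) / 2.0
        return np.minimum(p, 1.0 - p)

    def heterozygosity(self) -> pd.Series:
        """Per-strain fraction of heterozygous calls among non-missing."""
        het = (self.dosages == 1).sum(axis=0)
        tot = np.isfinite(self.dosages).sum(axis=0)
        with np.errstate(invalid="ignore"):
            frac = np.where(tot > 0, het / np.maximum(tot, 1), np.nan)
        return pd.Series(frac, index=self.strains, name="heterozygosity")

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            markers=self.markers.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[idx],
            strains=list(self.strains),
        )


@dataclass
class CoreMask:
    """Non-overlapping set of core-genome intervals (0-based half-open)."""

    intervals: pd.DataFrame  # chrom, start, end

    def __post_init__(self) -> None:
        self.intervals = normalize_intervals(self.intervals)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorized membership test for point positions."""
        keep = np.zeros(len(pos), dtype=bool)
        for c, grp in self.intervals.groupby("chrom"):
            sel = chrom == c
            if not sel.any():
                continue
            p = pos[sel]
            inside = np.zeros(p.size, dtype=bool)
            for s, e in zip(grp["start"], grp["end"]):
                inside |= (p >= s) & (p < e)
            keep[np.nonzero(sel)[0]] = inside
        return keep


def normalize_intervals(frame: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/touching intervals per chromosome."""
    rows = []
    for c, grp in frame.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if e <= s:
                raise ValueError(f"empty interval {c}:{s}-{e}")
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append({"chrom": c, "start": cur_s, "end": cur_e})
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append({"chrom": c, "start": cur_s, "end": cur_e})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class LDBlock:
    chrom: str
    start: int
    end: int
    members: list[int]            # marker row indices
    representative: int           # marker row index
    r2_threshold: float


@dataclass
class CNVMarker:
    chrom: str
    start: int
    end: int
    event: str                    # gain | loss
    presence: pd.Series           # strain -> {0,1}


@dataclass
class KinshipMatrix:
    values: np.ndarray
    strains: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strains)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over strains")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains, columns=self.strains)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF of biallelic SNP/indel calls into a dosage matrix.

    Multiallelic records are skipped with a warning.  Genotypes must carry a
    GT field; missing calls become NaN dosages.  Positions are converted to
    0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    strains = list(vcf.samples)
    rows, dosage_rows = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if var.gt_types is None or len(var.gt_types) != len(strains):
            raise ValueError(f"record {var.CHROM}:{var.POS} lacks GT genotypes")
        d = var.gt_types.astype(float)
        d[d == 3] = np.nan  # unknown
        kind = "snp" if len(var.REF) == 1 and len(var.ALT[0]) == 1 else "indel"
        rows.append(
            {"chrom": var.CHROM, "pos": var.POS - 1, "ref": var.REF,
             "alt": var.ALT[0], "kind": kind}
        )
        dosage_rows.append(d)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records", stacklevel=2)
    markers = pd.DataFrame(rows, columns=list(MARKER_COLUMNS))
    dos = np.array(dosage_rows) if dosage_rows else np.empty((0, len(strains)))
    return GenotypeMatrix(markers=markers, dosages=dos, strains=strains)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal diploid VCF (GT only) for the matrix."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(gm.markers["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.strains) + "\n")
        for i, row in gm.markers.iterrows():
            gts = "\t".join(
                code.get(d, "./.") if np.isfinite(d) else "./."
                for d in gm.dosages[i]
            )
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_bed_mask(path) -> CoreMask:
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
    )
    return CoreMask(intervals=frame)


def read_genes(path) -> pd.DataFrame:
    """Gene catalogue as BED + extra columns: chrom, start, end, gene_id,
    strand, orf_class, tf_superfamily (tab-separated, header optional)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene_id", "chrom", "start", "end", "strand"}
    if not need <= set(frame.columns):
        frame = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "gene_id", "strand",
                   "orf_class", "tf_superfamily"],
        )
    frame["tf_superfamily"] = frame.get("tf_superfamily", "").fillna("")
    return frame


# ---------------------------------------------------------------------------
# marker filtering and LD blocks
# ---------------------------------------------------------------------------

def filter_core_maf(
    gm: GenotypeMatrix, mask: CoreMask | None = None, maf_min: float = 0.05
) -> GenotypeMatrix:
    """Keep markers inside the core mask with MAF strictly above ``maf_min``.

    Marker order is preserved; an empty result warns rather than raises.
    """
    keep = gm.maf() > maf_min
    if mask is not None:
        chrom = gm.markers["chrom"].to_numpy()
        pos = gm.markers["pos"].to_numpy()
        keep &= mask.contains(chrom, pos)
    if not keep.any():
        warnings.warn("no markers survive the core/MAF filter", stacklevel=2)
    return gm.subset_markers(np.nonzero(keep)[0])


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_blocks(
    gm: GenotypeMatrix, r2_min: float = 0.8, max_gap_bp: int = 20_000
) -> tuple[list[LDBlock], GenotypeMatrix]:
    """Greedy left-to-right chaining of markers into LD blocks.

    A block grows while the next marker (position-sorted within chromosome)
    lies within ``max_gap_bp`` of the block's last member and has r² >=
    ``r2_min`` with the block's representative — the highest-MAF member so
    far (ties broken leftmost).  Singletons are blocks of one.  Returns the
    blocks and the matrix of representative markers (one row per block).
    """
    maf = gm.maf()
    blocks: list[LDBlock] = []
    order = gm.markers.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    cur: list[int] = []
    rep = -1

    def close() -> None:
        if cur:
            blocks.append(
                LDBlock(
                    chrom=str(gm.markers.loc[cur[0], "chrom"]),
                    start=int(gm.markers.loc[cur[0], "pos"]),
                    end=int(gm.markers.loc[cur[-1], "pos"]) + 1,
                    members=list(cur), representative=rep,
                    r2_threshold=r2_min,
                )
            )

    prev_chrom = None
    for i in order:
        chrom = gm.markers.loc[i, "chrom"]
        pos = gm.markers.loc[i, "pos"]
        if cur:
            last_pos = gm.markers.loc[cur[-1], "pos"]
            same = (
                chrom == prev_chrom
                and pos - last_pos <= max_gap_bp
                and _r2(gm.dosages[rep], gm.dosages[i]) >= r2_min
            )
        else:
            same = False
        if same:
            cur.append(i)
            if maf[i] > maf[rep]:
                rep = i
        else:
            close()
            cur, rep = [i], i
        prev_chrom = chrom
    close()
    rep_idx = [b.representative for b in blocks]
    return blocks, gm.subset_markers(rep_idx)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix, mean-diagonal normalized.

    Dosages are centered by twice the allele frequency and the cross-product
    scaled by 2 Σ p(1-p); constant markers are excluded silently; missing
    dosages are mean-imputed for the cross-product; tiny negative
    eigenvalues are clipped so the result is PSD.
    """
    if len(gm.strains) < 2:
        raise ValueError("kinship needs at least 2 strains")
    X = gm.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=1)
    idx = np.nanstd(X, axis=1) > 0
    X = X[idx]
    mean = mean[idx]
    if X.shape[0] == 0:
        raise ValueError("no polymorphic markers for kinship")
    nan_mask = ~np.isfinite(X)
    if nan_mask.any():
        X[nan_mask] = np.take(mean, np.nonzero(nan_mask)[0])
    p = mean / 2.0
    Z = X - 2.0 * p[:, None]
    denom = 2.0 * np.sum(p * (1 - p))
    K = Z.T @ Z / denom
    K /= np.mean(np.diag(K))
    vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    K = (vecs * vals) @ vecs.T
    return KinshipMatrix(values=(K + K.T) / 2.0, strains=list(gm.strains))


# ---------------------------------------------------------------------------
# CNV markers and gene events
# ---------------------------------------------------------------------------

def classify_cnv(segments: pd.DataFrame, ploidy: dict[str, int] | None = None) -> pd.DataFrame:
    """Label segments as gain/loss/deletion against each strain's ploidy.

    ``segments``: chrom, start, end, copy_number, strain.  Unknown strains
    default to ploidy 2.  copy 0 -> deletion; 0 < copy < ploidy -> loss;
    copy > ploidy -> gain; copy == ploidy rows are dropped (no event).
    """
    ploidy = ploidy or {}
    seg = segments.copy()
    pl = seg["strain"].map(lambda s: ploidy.get(s, 2)).to_numpy()
    cn = seg["copy_number"].to_numpy()
    event = np.where(cn == 0, "deletion", np.where(cn < pl, "loss", np.where(cn > pl, "gain", "none")))
    seg["event"] = event
    return seg[seg["event"] != "none"].reset_index(drop=True)


def cnv_markers(
    segments: pd.DataFrame,
    event: str,
    strains: list[str],
    ploidy: dict[str, int] | None = None,
    min_class_frac: float = 0.05,
) -> list[CNVMarker]:
    """Binary CNV presence markers from the overlap structure of segments.

    Gain markers use gain events; loss markers pool loss and deletion
    events (both reduce copy number).  The genome is cut at the union of
    event breakpoints into atomic segments; each atomic segment's presence
    vector is the set of strains whose event covers it; adjacent atomic
    segments with identical presence are merged; constant presence vectors
    and markers whose minor class frequency is below ``min_class_frac`` are
    dropped.
    """
    if event not in ("gain", "loss"):
        raise ValueError("event must be 'gain' or 'loss'")
    seg = classify_cnv(segments, ploidy)
    if event == "gain":
        seg = seg[seg["event"] == "gain"]
    else:
        seg = seg[seg["event"].isin(["loss", "deletion"])]
    markers: list[CNVMarker] = []
    n = len(strains)
    sidx = {s: k for k, s in enumerate(strains)}
    for chrom, grp in seg.groupby("chrom"):
        cuts = np.unique(np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy()]))
        if cuts.size < 2:
            continue
        atom_start, atom_end = cuts[:-1], cuts[1:]
        presence = np.zeros((atom_start.size, n), dtype=int)
        for _, row in grp.iterrows():
            cover = (atom_start >= row["start"]) & (atom_end <= row["end"])
            presence[cover, sidx[row["strain"]]] = 1
        # merge touching runs with identical presence
        runs: list[tuple[int, int, np.ndarray]] = []
        for a in range(atom_start.size):
            if runs and runs[-1][1] == atom_start[a] and np.array_equal(runs[-1][2], presence[a]):
                runs[-1] = (runs[-1][0], int(atom_end[a]), runs[-1][2])
            else:
                runs.append((int(atom_start[a]), int(atom_end[a]), presence[a]))
        for start, end, vec in runs:
            k = int(vec.sum())
            if k == 0 or k == n:
                continue
            if min(k, n - k) / n < min_class_frac:
                continue
            markers.append(
                CNVMarker(
                    chrom=str(chrom), start=start, end=end, event=event,
                    presence=pd.Series(vec, index=strains),
                )
            )
    return markers


def gene_cnv_events(
    genes: pd.DataFrame,
    segments: pd.DataFrame,
    ploidy: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Assign CNV events to genes: gene x strain labels.

    A gene fully covered by an event region gets that event.  A gene only
    partially overlapped gets loss/deletion (at least one copy truncated)
    but never gain (the extra copy is incomplete).  Deletion (copy 0)
    dominates loss, which dominates gain, when multiple events overlap.
    Same-event regions are merged per strain before the coverage test.
    """
    seg = classify_cnv(segments, ploidy)
    labels = pd.DataFrame(
        "none", index=genes["gene_id"],
        columns=sorted(seg["strain"].unique()) if len(seg) else [],
    )
    rank = {"none": 0, "gain": 1, "loss": 2, "deletion": 3}
    for (strain, event), grp in seg.groupby(["strain", "event"]):
        merged = normalize_intervals(grp[["chrom", "start", "end"]])
        for _, g in genes.iterrows():
            hits = merged[
                (merged["chrom"] == g["chrom"])
                & (merged["start"] < g["end"])
                & (merged["end"] > g["start"])
            ]
            if hits.empty:
                continue
            full = ((hits["start"] <= g["start"]) & (hits["end"] >= g["end"])).any()
            if event == "gain" and not full:
                continue
            cur = labels.loc[g["gene_id"], strain]
            if rank[event] > rank[cur]:
                labels.loc[g["gene_id"], strain] = event
    return labels
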