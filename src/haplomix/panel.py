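"""Haplotype panels: containers, file formats, and sample/SNP quality control.

A :class:`HaplotypePanel` holds phased biallelic haplotypes (one row per
haplotype, two consecutive rows per diploid sample) together with per-site
chromosome, physical position and genetic-map position (in Morgans), and
per-sample population labels and donor/recipient roles.

Coordinates are 0-based half-open internally; VCF I/O is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: Smallest allowed inter-site genetic distance (Morgans).  Zero distances
#: would make the copying HMM's transition degenerate, so map attachment
#: floors them at this value.
MIN_GENETIC_DISTANCE = 1e-9


class PanelFormatError(ValueError):
    """A haplotype input file violates the expected format."""


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix with site and sample metadata.

    Parameters
    ----------
    alleles
        ``(n_haplotypes, n_sites)`` int8 matrix with entries 0, 1 or -1
        (missing).  Haplotypes ``2*i`` and ``2*i + 1`` belong to sample ``i``.
    sample_ids
        One id per diploid sample.
    populations
        Population label per sample.
    roles
        ``"donor"`` or ``"recipient"`` per sample.
    sites
        DataFrame with columns ``chrom``, ``pos`` (bp, 1-based),
        ``gpos`` (Morgans; NaN until a map is attached).
    """

    alleles: np.ndarray
    sample_ids: list[str]
    populations: list[str]
    roles: list[str]
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x site matrix")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"{self.alleles.shape[0]} haplotype rows for "
                f"{len(self.sample_ids)} samples; expected exactly 2 per sample"
            )
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("populations must align with sample_ids")
        if len(self.roles) != len(self.sample_ids):
            raise ValueError("roles must align with sample_ids")
        bad = set(np.unique(self.alleles)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"alleles must be in {{0,1,-1}}; found {sorted(bad)}")
        if len(self.sites) != self.alleles.shape[1]:
            raise ValueError("sites table must have one row per allele column")
        self.sites = self.sites.reset_index(drop=True)

    # ----- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}_{h}" for s in self.sample_ids for h in (0, 1)]

    def sample_of_haplotype(self, hap_index: int) -> str:
        return self.sample_ids[hap_index // 2]

    def population_of(self, sample_id: str) -> str:
        return self.populations[self.sample_ids.index(sample_id)]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def haplotype_rows(self, sample_id: str) -> tuple[int, int]:
        i = self.sample_index(sample_id)
        return 2 * i, 2 * i + 1

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.sites["chrom"]))

    def chromosome_sites(self, chrom) -> np.ndarray:
        """Indices of the sites on one chromosome, in site order."""
        return np.flatnonzero(self.sites["chrom"].to_numpy() == chrom)

    def gpos(self) -> np.ndarray:
        return self.sites["gpos"].to_numpy(dtype=float)

    # ----- subsetting ------------------------------------------------------

    def subset_samples(self, keep: list[str]) -> "HaplotypePanel":
        idx = [self.sample_index(s) for s in keep]
        rows = np.array([r for i in idx for r in (2 * i, 2 * i + 1)], dtype=int)
        return HaplotypePanel(
            alleles=self.alleles[rows],
            sample_ids=[self.sample_ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            roles=[self.roles[i] for i in idx],
            sites=self.sites.copy(),
        )

    def subset_sites(self, site_idx: np.ndarray) -> "HaplotypePanel":
        site_idx = np.asarray(site_idx, dtype=int)
        return replace(
            self,
            alleles=self.alleles[:, site_idx],
            sites=self.sites.iloc[site_idx].reset_index(drop=True),
        )

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, r in zip(self.sample_ids, self.roles) if r == role]

    def call_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site and per-sample fraction of non-missing haplotype calls."""
        obs = self.alleles >= 0
        site_rate = obs.mean(axis=0)
        sample_rate = obs.reshape(self.n_samples, 2, -1).mean(axis=(1, 2))
        return site_rate, sample_rate


def merge_panels(a: HaplotypePanel, b: HaplotypePanel) -> HaplotypePanel:
    """Stack two panels defined on the identical site set."""
    if len(a.sites) != len(b.sites) or not (
        a.sites[["chrom", "pos"]].equals(b.sites[["chrom", "pos"]])
    ):
        raise ValueError("panels must share an identical site table")
    dup = set(a.sample_ids) & set(b.sample_ids)
    if dup:
        raise ValueError(f"duplicate sample ids: {sorted(dup)[:5]}")
    return HaplotypePanel(
        alleles=np.vstack([a.alleles, b.alleles]),
        sample_ids=a.sample_ids + b.sample_ids,
        populations=a.populations + b.populations,
        roles=a.roles + b.roles,
        sites=a.sites.copy(),
    )


# ---------------------------------------------------------------------------
# VCF I/O (plain-text, phased, biallelic SNPs only)
# ---------------------------------------------------------------------------

def write_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel as an uncompressed phased VCF (GT only, '|' phased)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in panel.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        alleles = panel.alleles
        chroms = panel.sites["chrom"].tolist()  # column access keeps dtype
        positions = panel.sites["pos"].tolist()
        for j in range(panel.n_sites):
            gts = []
            for i in range(panel.n_samples):
                a0, a1 = alleles[2 * i, j], alleles[2 * i + 1, j]
                s0 = "." if a0 < 0 else str(int(a0))
                s1 = "." if a1 < 0 else str(int(a1))
                gts.append(f"{s0}|{s1}")
            fh.write(
                f"{chroms[j]}\t{int(positions[j])}\tsnp{j}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_sample_table(panel: HaplotypePanel, path) -> None:
    pd.DataFrame(
        {
            "sample": panel.sample_ids,
            "population": panel.populations,
            "role": panel.roles,
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population"}
    if not required <= set(tab.columns):
        raise PanelFormatError(f"sample table needs columns {sorted(required)}")
    if "role" not in tab.columns:
        tab["role"] = "donor"
    return tab


def read_panel(vcf_path, sample_table_path=None) -> HaplotypePanel:
    """Read a phased VCF (or IMPUTE .haps; see :func:`read_haps`) into a panel.

    All records must be biallelic SNPs with phased GT fields; unphased
    genotypes or duplicated positions raise :class:`PanelFormatError` naming
    the offending record.  ``sample_table_path`` supplies population labels
    and donor/recipient roles; without it all samples are labelled
    ``pop="unknown"``, ``role="donor"``.  Parsing goes through cyvcf2 when
    it is installed, else a minimal text reader.
    """
    path = str(vcf_path)
    if path.endswith((".haps", ".hap")):
        return read_haps(path, sample_table_path)
    try:
        import cyvcf2
    except ImportError:
        cyvcf2 = None
    if cyvcf2 is not None:
        return _finish_panel(*_read_vcf_cyvcf2(path), sample_table_path)
    return _finish_panel(*_read_vcf_text(path), sample_table_path)


def _read_vcf_cyvcf2(path):
    import cyvcf2

    reader = cyvcf2.VCF(path)
    sample_ids = list(reader.samples)
    chroms: list = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    seen: set[tuple] = set()
    for var in reader:
        if len(var.REF) != 1 or len(var.ALT) != 1 or len(var.ALT[0]) != 1:
            raise PanelFormatError(
                f"record {var.CHROM}:{var.POS} is not a biallelic SNP "
                f"(REF={var.REF} ALT={','.join(var.ALT)})"
            )
        key = (var.CHROM, var.POS)
        if key in seen:
            raise PanelFormatError(f"duplicate position {var.CHROM}:{var.POS}")
        seen.add(key)
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if not phased and (a0 >= 0 or a1 >= 0):
                raise PanelFormatError(
                    f"unphased genotype at {var.CHROM}:{var.POS}, sample "
                    f"{sample_ids[i]}"
                )
            col[2 * i] = MISSING if a0 < 0 else np.int8(a0)
            col[2 * i + 1] = MISSING if a1 < 0 else np.int8(a1)
        chroms.append(var.CHROM)
        positions.append(int(var.POS))
        columns.append(col)
    if not columns:
        raise PanelFormatError(f"no variant records in {path}")
    return sample_ids, chroms, positions, columns


def _read_vcf_text(path):
    sample_ids: list[str] = []
    chroms: list = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    seen: set[tuple] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.rstrip("\n").split("\t")[9:]
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _vid, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                raise PanelFormatError(
                    f"record {chrom}:{pos} is not a biallelic SNP (REF={ref} ALT={alt})"
                )
            key = (chrom, int(pos))
            if key in seen:
                raise PanelFormatError(f"duplicate position {chrom}:{pos}")
            seen.add(key)
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            col = np.empty(2 * len(sample_ids), dtype=np.int8)
            for i, sample_field in enumerate(fields[9:]):
                gt = sample_field.split(":")[gt_i]
                if "/" in gt:
                    raise PanelFormatError(
                        f"unphased genotype {gt!r} at {chrom}:{pos}, sample "
                        f"{sample_ids[i]}"
                    )
                parts = gt.split("|")
                if len(parts) != 2:
                    raise PanelFormatError(f"bad GT {gt!r} at {chrom}:{pos}")
                for h, p in enumerate(parts):
                    col[2 * i + h] = MISSING if p == "." else np.int8(int(p))
            chroms.append(chrom)
            positions.append(int(pos))
            columns.append(col)
    if not columns:
        raise PanelFormatError(f"no variant records in {path}")
    return sample_ids, chroms, positions, columns


def _finish_panel(sample_ids, chroms, positions, columns, sample_table_path):
    alleles = np.column_stack(columns)
    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "gpos": np.nan})
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    alleles = alleles[:, order]
    populations = ["unknown"] * len(sample_ids)
    roles = ["donor"] * len(sample_ids)
    if sample_table_path is not None:
        tab = read_sample_table(sample_table_path).set_index("sample")
        populations = [str(tab.loc[s, "population"]) for s in sample_ids]
        roles = [str(tab.loc[s, "role"]) for s in sample_ids]
    return HaplotypePanel(alleles, list(sample_ids), populations, roles, sites)


# ---------------------------------------------------------------------------
# IMPUTE-style .haps/.sample
# ---------------------------------------------------------------------------

def write_haps(panel: HaplotypePanel, haps_path, sample_path) -> None:
    """Write IMPUTE-style .haps (chrom id pos A0 A1 h1 h2 ...) and .sample."""
    with open(haps_path, "w") as fh:
        chroms = panel.sites["chrom"].tolist()
        positions = panel.sites["pos"].tolist()
        for j in range(panel.n_sites):
            calls = " ".join(
                "?" if a < 0 else str(int(a)) for a in panel.alleles[:, j]
            )
            fh.write(f"{chroms[j]} snp{j} {int(positions[j])} A G {calls}\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing population role\n")
        fh.write("0 0 0 D D\n")
        for s, p, r in zip(panel.sample_ids, panel.populations, panel.roles):
            fh.write(f"{s} {s} 0 {p} {r}\n")


def read_haps(haps_path, sample_path) -> HaplotypePanel:
    chroms, positions, columns = [], [], []
    with open(haps_path) as fh:
        for line in fh:
            parts = line.split()
            chroms.append(parts[0])
            positions.append(int(parts[2]))
            columns.append(
                np.array(
                    [MISSING if c == "?" else np.int8(int(c)) for c in parts[5:]],
                    dtype=np.int8,
                )
            )
    tab = pd.read_csv(sample_path, sep=r"\s+").iloc[1:]  # drop type row
    sample_ids = [str(s) for s in tab["ID_1"]]
    populations = [str(p) for p in tab.get("population", ["unknown"] * len(sample_ids))]
    roles = [str(r) for r in tab.get("role", ["donor"] * len(sample_ids))]
    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "gpos": np.nan})
    return HaplotypePanel(np.column_stack(columns), sample_ids, populations, roles, sites)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path) -> pd.DataFrame:
    """Read a HapMap-format map: chrom, position (bp), rate (cM/Mb), cM."""
    tab = pd.read_csv(path, sep=r"\s+")
    tab.columns = ["chrom", "pos", "rate_cM_Mb", "cM"][: len(tab.columns)]
    return tab


def write_genetic_map(map_table: pd.DataFrame, path) -> None:
    out = map_table.copy()
    out.columns = ["chrom", "position", "rate_cM_Mb", "cM"][: len(out.columns)]
    out.to_csv(path, sep=" ", index=False)


def attach_genetic_map(
    panel: HaplotypePanel, genetic_map, min_g: float = MIN_GENETIC_DISTANCE
) -> HaplotypePanel:
    """Set per-site genetic positions (Morgans) by interpolating a map.

    Cumulative cM is linearly interpolated at each site's physical position
    (sites beyond the map ends take the end value) and converted to Morgans.
    Inter-site distances of zero within a chromosome are then floored at
    ``min_g`` so downstream HMM transitions stay non-degenerate.
    """
    if isinstance(genetic_map, (str, bytes)) or hasattr(genetic_map, "__fspath__"):
        genetic_map = read_genetic_map(genetic_map)
    gmap = genetic_map
    gpos = np.full(panel.n_sites, np.nan)
    for chrom in panel.chromosomes:
        sub = gmap[gmap["chrom"].astype(str) == str(chrom)]
        if sub.empty:
            raise ValueError(f"chromosome {chrom!r} absent from genetic map")
        sub = sub.sort_values(gmap.columns[1])
        idx = panel.chromosome_sites(chrom)
        pos = panel.sites["pos"].to_numpy()[idx].astype(float)
        cm = np.interp(pos, sub.iloc[:, 1].to_numpy(float), sub["cM"].to_numpy(float))
        g = cm / 100.0
        # enforce strict increase after interpolation
        g = np.maximum.accumulate(g)
        for k in range(1, len(g)):
            if g[k] - g[k - 1] < min_g:
                g[k] = g[k - 1] + min_g
        gpos[idx] = g
    sites = panel.sites.copy()
    sites["gpos"] = gpos
    return replace(panel, sites=sites)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def filter_call_rate(
    panel: HaplotypePanel, min_rate: float = 0.98
) -> tuple[HaplotypePanel, dict]:
    """Drop SNPs, then samples, whose call rate falls below ``min_rate``.

    The default 0.98 retains only sites and individuals with genotyping
    success rate above 98%.  SNPs are filtered before samples.  Returns the
    filtered panel and a report with the counts dropped.
    """
    if not (0 < min_rate <= 1):
        raise ValueError("min_rate must be in (0, 1]")
    site_rate, _ = panel.call_rates()
    keep_sites = np.flatnonzero(site_rate >= min_rate)
    if keep_sites.size == 0:
        raise ValueError("empty panel: every SNP fails the call-rate filter")
    out = panel.subset_sites(keep_sites)
    _, sample_rate = out.call_rates()
    keep_samples = [s for s, r in zip(out.sample_ids, sample_rate) if r >= min_rate]
    if not keep_samples:
        raise ValueError("empty panel: every sample fails the call-rate filter")
    report = {
        "snps_dropped": panel.n_sites - keep_sites.size,
        "samples_dropped": out.n_samples - len(keep_samples),
    }
    if len(keep_samples) < out.n_samples:
        out = out.subset_samples(keep_samples)
    return out, report


def read_kinship_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    tab.columns = ["id1", "id2", "kinship"][: len(tab.columns)]
    return tab


def prune_kinship(
    panel: HaplotypePanel, kinship: pd.DataFrame, threshold: float = 0.0884
) -> tuple[HaplotypePanel, list[str]]:
    """Remove related individuals until no pair's kinship exceeds ``threshold``.

    ``kinship`` holds pairwise coefficients (columns id1, id2, kinship; a
    precomputed table, e.g. from KING — the default 0.0884 is the usual
    third-degree-relative cutoff).  From each pair above the threshold the
    member involved in more such pairs is removed greedily; ties break by
    lower call rate, then lexicographic id.  Returns the pruned panel and
    the removed sample ids.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    known = set(panel.sample_ids)
    pairs = []
    for id1, id2, k in kinship[["id1", "id2", "kinship"]].itertuples(index=False):
        if id1 not in known:
            raise KeyError(f"kinship table references unknown sample {id1!r}")
        if id2 not in known:
            raise KeyError(f"kinship table references unknown sample {id2!r}")
        if id1 != id2 and float(k) > threshold:
            pairs.append((str(id1), str(id2)))
    _, sample_rate = panel.call_rates()
    call_rate = dict(zip(panel.sample_ids, sample_rate))
    removed: list[str] = []
    pairs = set(map(frozenset, pairs))
    while pairs:
        degree: dict[str, int] = {}
        for p in pairs:
            for s in p:
                degree[s] = degree.get(s, 0) + 1
        # most pairs first; ties -> lower call rate, then lexicographically first
        victim = min(degree, key=lambda s: (-degree[s], call_rate[s], s))
        removed.append(victim)
        pairs = {p for p in pairs if victim not in p}
    keep = [s for s in panel.sample_ids if s not in removed]
    return (panel.subset_samples(keep) if removed else panel), removed
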