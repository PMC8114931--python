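"""Allele-frequency panels: VCF input, jackknife blocks and fixed windows.

The central container is :class:`AlleleFrequencyPanel`, a per-site by
per-lineage matrix of derived-allele frequencies built from a multi-sample
VCF and a population map (sample -> lineage).  Downstream statistics
(Patterson's D, f4, Dxy, fd, pi) all consume this panel.

Coordinates follow the named standards: VCF positions are kept 1-based
internally; windows and BED output are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


class PanelError(ValueError):
    """Raised for malformed inputs to panel construction."""


@dataclass
class AlleleFrequencyPanel:
    """Per-site derived-allele frequencies for a set of lineages.

    Attributes
    ----------
    lineage_ids : list of str
        Ordered lineage labels (columns of ``freq``).
    chrom : ndarray of str
        Per-site chromosome name.
    pos : ndarray of int
        Per-site 1-based position, strictly increasing within a chromosome.
    freq : ndarray, shape (n_sites, n_lineages)
        Derived-allele frequency in [0, 1]; NaN where no allele copies were
        called for that lineage.
    called_n : ndarray of int, shape (n_sites, n_lineages)
        Number of called allele copies behind each frequency.
    block_id : ndarray of int or None
        Jackknife-block index per site (``assign_blocks``).
    outgroup_id : str
        Label of the outgroup lineage; must be in ``lineage_ids``.
    """

    lineage_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    freq: np.ndarray
    called_n: np.ndarray
    outgroup_id: str
    block_id: np.ndarray | None = None
    polarized: bool = False

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freq = np.asarray(self.freq, dtype=float)
        self.called_n = np.asarray(self.called_n, dtype=np.int64)
        if self.outgroup_id not in self.lineage_ids:
            raise PanelError(f"outgroup {self.outgroup_id!r} not among lineages")
        if self.freq.shape != (len(self.pos), len(self.lineage_ids)):
            raise PanelError("freq shape does not match sites x lineages")
        with np.errstate(invalid="ignore"):
            bad = (self.freq < 0) | (self.freq > 1)
        if bad.any():
            raise PanelError("frequencies must be missing or in [0, 1]")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise PanelError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_lineages(self) -> int:
        return len(self.lineage_ids)

    def lineage_index(self, label: str) -> int:
        try:
            return self.lineage_ids.index(label)
        except ValueError:
            raise PanelError(f"unknown lineage {label!r}") from None

    def column(self, label: str) -> np.ndarray:
        """Frequency vector for one lineage (NaN = missing)."""
        return self.freq[:, self.lineage_index(label)]

    def subset_sites(self, mask: np.ndarray) -> "AlleleFrequencyPanel":
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            freq=self.freq[mask],
            called_n=self.called_n[mask],
            block_id=None if self.block_id is None else self.block_id[mask],
        )

    # ---------------------------------------------------------------- I/O

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=self.lineage_ids)
        df.insert(0, "pos", self.pos)
        df.insert(0, "chrom", self.chrom)
        return df

    def to_tsv(self, path) -> None:
        """Persist as TSV with header ``chrom pos lineage1..lineageK``."""
        # %.17g round-trips float64 exactly
        self.to_dataframe().to_csv(
            path, sep="\t", index=False, na_rep="nan", float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path, outgroup: str) -> "AlleleFrequencyPanel":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        lineages = [c for c in df.columns if c not in ("chrom", "pos")]
        freq = df[lineages].to_numpy(dtype=float)
        called = np.where(np.isnan(freq), 0, 2)  # copy counts are not persisted
        return cls(
            lineage_ids=lineages,
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(),
            freq=freq,
            called_n=called,
            outgroup_id=outgroup,
        )


@dataclass
class WindowIndex:
    """Fixed, non-overlapping genomic windows over a panel's sites.

    ``windows`` are (chrom, start, end) in 0-based half-open coordinates;
    ``site_membership[i]`` lists panel site indices falling in window i;
    ``missing_rate[i]`` is the fraction of those sites at which any lineage
    frequency is missing.  ``retained`` flags windows whose missing rate is
    below the retention threshold.
    """

    windows: list[tuple[str, int, int]]
    site_membership: list[np.ndarray]
    missing_rate: np.ndarray
    retained: np.ndarray
    window_size: int
    max_missing: float

    def __len__(self) -> int:
        return len(self.windows)

    def to_bed(self, path, retained_only: bool = True) -> None:
        with open(path, "w") as fh:
            for i, (c, s, e) in enumerate(self.windows):
                if retained_only and not self.retained[i]:
                    continue
                fh.write(f"{c}\t{s}\t{e}\twin{i}\t{len(self.site_membership[i])}\t.\n")


# -------------------------------------------------------------------- VCF


def read_popmap(path) -> dict[str, str]:
    """Read a ``sample<TAB>lineage`` table into a dict."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PanelError(f"popmap line {ln}: expected 'sample<TAB>lineage'")
            sample, lineage = parts
            if sample in popmap:
                raise PanelError(f"popmap line {ln}: sample {sample!r} listed twice")
            popmap[sample] = lineage
    if not popmap:
        raise PanelError("empty popmap")
    return popmap


def read_panel(
    vcf_path,
    popmap_path,
    outgroup: str,
    polarize: bool = True,
) -> AlleleFrequencyPanel:
    """Build an :class:`AlleleFrequencyPanel` from a VCF and population map.

    Only biallelic SNVs are retained.  Each lineage's frequency is
    (ALT copies) / (called copies) over the lineage's samples, or missing
    when nothing was called.  With ``polarize`` the outgroup-majority allele
    is taken as ancestral: sites where the outgroup is missing or polymorphic
    are dropped, and frequencies are flipped where the outgroup carries ALT,
    so that ``freq`` is the derived-allele frequency.

    Raises
    ------
    PanelError
        If a popmap sample is absent from the VCF, the outgroup lineage is
        absent, or a record cannot be parsed (the error names the record).
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    lineages = sorted(set(popmap.values()))
    if outgroup not in lineages:
        raise PanelError(f"outgroup lineage {outgroup!r} not present in popmap")

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in popmap if s not in vcf_samples]
    if missing_samples:
        raise PanelError(f"popmap samples absent from VCF: {missing_samples}")

    # sample column indices per lineage
    lin_cols = {
        lin: [vcf_samples.index(s) for s, l in popmap.items() if l == lin]
        for lin in lineages
    }
    og_col = lineages.index(outgroup)

    chroms: list[str] = []
    positions: list[int] = []
    freqs: list[np.ndarray] = []
    called: list[np.ndarray] = []

    for rec_no, var in enumerate(vcf, 1):
        try:
            if len(var.ALT) != 1:
                continue  # multi-allelic / triallelic
            if len(var.REF) != 1 or len(var.ALT[0]) != 1:
                continue  # indel
            if var.ALT[0] not in "ACGT" or var.REF not in "ACGT":
                continue
            gts = np.array(var.genotypes, dtype=object)
        except Exception as exc:  # pragma: no cover - malformed record
            raise PanelError(f"malformed VCF record #{rec_no}: {exc}") from exc

        f_row = np.full(len(lineages), np.nan)
        n_row = np.zeros(len(lineages), dtype=np.int64)
        for j, lin in enumerate(lineages):
            alt = 0
            n = 0
            for col in lin_cols[lin]:
                for allele in gts[col][:-1]:  # last entry is phase flag
                    if allele is None or allele < 0:
                        continue
                    n += 1
                    alt += int(allele)
            n_row[j] = n
            if n > 0:
                f_row[j] = alt / n

        if np.all(np.isnan(f_row)):
            continue
        chroms.append(var.CHROM)
        positions.append(var.POS)
        freqs.append(f_row)
        called.append(n_row)

    if not freqs:
        raise PanelError("no biallelic SNVs retained from VCF")

    freq = np.vstack(freqs)
    called_n = np.vstack(called)
    chrom = np.array(chroms, dtype=object)
    pos = np.array(positions, dtype=np.int64)

    if polarize:
        og = freq[:, og_col]
        keep = np.isfinite(og) & ((og == 0.0) | (og == 1.0))
        freq, called_n = freq[keep], called_n[keep]
        chrom, pos = chrom[keep], pos[keep]
        flip = freq[:, og_col] == 1.0
        freq[flip] = 1.0 - freq[flip]

    return AlleleFrequencyPanel(
        lineage_ids=lineages,
        chrom=chrom,
        pos=pos,
        freq=freq,
        called_n=called_n,
        outgroup_id=outgroup,
        polarized=polarize,
    )


# ----------------------------------------------------------------- blocks


def assign_blocks(panel: AlleleFrequencyPanel, n_blocks: int) -> AlleleFrequencyPanel:
    """Split retained sites into ``n_blocks`` contiguous jackknife blocks.

    Blocks never span a chromosome boundary; within the per-chromosome
    allocation, block sizes differ by at most one site.  The chromosome
    allocation is proportional to site counts (largest remainders), with
    every chromosome getting at least one block.
    """
    if n_blocks < 2:
        raise PanelError("jackknife needs at least 2 blocks")
    if n_blocks > panel.n_sites:
        raise PanelError("more blocks than retained sites")

    chrom_order = list(pd.unique(panel.chrom))
    counts = np.array([(panel.chrom == c).sum() for c in chrom_order])
    if n_blocks < len(chrom_order):
        raise PanelError(
            f"need at least one block per chromosome ({len(chrom_order)})"
        )
    # proportional allocation, >=1 per chromosome, largest remainders
    raw = counts / counts.sum() * n_blocks
    alloc = np.maximum(np.floor(raw).astype(int), 1)
    alloc = np.minimum(alloc, counts)
    while alloc.sum() < n_blocks:
        rema = np.where(alloc < counts, raw - alloc, -np.inf)
        alloc[int(np.argmax(rema))] += 1
    while alloc.sum() > n_blocks:
        rema = np.where(alloc > 1, raw - alloc, np.inf)
        alloc[int(np.argmin(rema))] -= 1

    block_id = np.empty(panel.n_sites, dtype=np.int64)
    next_block = 0
    for c, k in zip(chrom_order, alloc):
        idx = np.flatnonzero(panel.chrom == c)
        m = len(idx)
        base, extra = divmod(m, k)
        start = 0
        for b in range(k):
            size = base + (1 if b < extra else 0)
            block_id[idx[start : start + size]] = next_block
            start += size
            next_block += 1
    return replace(panel, block_id=block_id)


def assign_blocks_by_length(
    panel: AlleleFrequencyPanel, block_bp: int
) -> AlleleFrequencyPanel:
    """Alternative blocking by fixed physical length in base pairs."""
    if block_bp <= 0:
        raise PanelError("block_bp must be positive")
    block_id = np.empty(panel.n_sites, dtype=np.int64)
    next_base = 0
    for c in pd.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        local = (panel.pos[idx] - 1) // block_bp
        _, dense = np.unique(local, return_inverse=True)
        block_id[idx] = dense + next_base
        next_base += dense.max() + 1
    return replace(panel, block_id=block_id)


# ---------------------------------------------------------------- windows


def build_windows(
    panel: AlleleFrequencyPanel,
    window_size: int,
    max_missing: float = 0.01,
) -> WindowIndex:
    """Tile each chromosome with fixed windows and apply the retention filter.

    Windows are 0-based half-open ``[k*size, (k+1)*size)``.  A window's
    missing rate is the fraction of its sites with at least one missing
    lineage frequency; windows with ``missing_rate >= max_missing`` are
    flagged excluded (the <1% SNV-missingness retention rule by default).
    Only windows containing at least one site are emitted.
    """
    if window_size <= 0:
        raise PanelError("window_size must be positive")
    any_missing = np.isnan(panel.freq).any(axis=1)

    windows: list[tuple[str, int, int]] = []
    members: list[np.ndarray] = []
    rates: list[float] = []
    for c in pd.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        win_of = (panel.pos[idx] - 1) // window_size
        for w in np.unique(win_of):
            sites = idx[win_of == w]
            windows.append((c, int(w) * window_size, (int(w) + 1) * window_size))
            members.append(sites)
            rates.append(float(any_missing[sites].mean()))
    rates_arr = np.array(rates)
    return WindowIndex(
        windows=windows,
        site_membership=members,
        missing_rate=rates_arr,
        retained=rates_arr < max_missing,
        window_size=window_size,
        max_missing=max_missing,
    )
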