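"""File-format adapters.

Coordinates are 0-based half-open internally and in BED-like outputs;
1-based only at VCF/TSV boundaries. VCF handling goes through pysam;
tabular formats through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .postprocess import PiecewiseTmrca, TmrcaTrack
from .simulate import DemographicModel, GeneticMap, HaplotypePanel

__all__ = [
    "read_panel",
    "write_panel_vcf",
    "save_panel_npz",
    "load_panel_npz",
    "read_genetic_map",
    "read_demography",
    "write_segments_bed",
    "write_dating_tsv",
    "write_annot",
]


def read_panel(
    vcf_path,
    genetic_map: Optional[GeneticMap] = None,
    recombination_rate: float = 1e-8,
) -> tuple[HaplotypePanel, np.ndarray]:
    """Load a phased biallelic VCF as a derived-allele panel.

    Alleles are recoded so 1 = derived using the AA INFO tag (ancestral
    allele): when AA equals ALT the genotypes are complemented. Variants with
    a missing or low-confidence (lowercase) ancestral call keep their
    REF-as-ancestral coding but are flagged; the returned boolean array marks
    variants with a high-confidence ancestral call (use it to exclude
    variants from dating). Multiallelic records are skipped; unphased
    genotypes are an error.
    """
    alleles_cols: list[np.ndarray] = []
    positions: list[float] = []
    known: list[bool] = []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            calls = []
            for sample in rec.samples.values():
                if not sample.phased:
                    raise ValueError(
                        f"unphased genotype at {rec.chrom}:{rec.pos}"
                    )
                calls.extend(sample["GT"])
            col = np.array(calls, dtype=np.uint8)
            aa = rec.info.get("AA")
            if isinstance(aa, tuple):
                aa = aa[0]
            high_conf = False
            if aa:
                aa_str = str(aa).split("|")[0]
                high_conf = aa_str.isupper()
                aa_up = aa_str.upper()
                if aa_up == alt.upper():
                    col = 1 - col  # REF carriers are the derived ones
                elif aa_up != ref.upper():
                    high_conf = False  # ancestral allele not seen here
            positions.append(float(rec.pos - 1))
            alleles_cols.append(col)
            known.append(high_conf)
    if n_skipped:
        import logging

        logging.getLogger(__name__).info("skipped %d multiallelic records", n_skipped)
    if not positions:
        raise ValueError(f"no usable biallelic record in {vcf_path}")
    pos = np.array(positions)
    alleles = np.stack(alleles_cols, axis=1)
    if genetic_map is not None:
        map_cm = genetic_map.cm_at(pos)
    else:
        map_cm = pos * recombination_rate * 100.0
    return HaplotypePanel(alleles, pos, map_cm), np.array(known, dtype=bool)


def write_panel_vcf(
    panel: HaplotypePanel,
    path,
    chrom: str = "1",
    ancestral_known: Optional[np.ndarray] = None,
) -> None:
    """Write a panel as a phased VCF with the AA (ancestral allele) tag.

    Sites are encoded REF=A (ancestral), ALT=G (derived); variants flagged
    as not high-confidence get a lowercase AA value.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.contigs.add(chrom, length=int(panel.positions[-1]) + 2)
    n_dip = panel.n_haplotypes // 2
    for d in range(n_dip):
        header.add_sample(f"sample{d}")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in range(panel.n_sites):
            rec = out.new_record(
                contig=chrom,
                start=int(panel.positions[s]),
                stop=int(panel.positions[s]) + 1,
                alleles=("A", "G"),
            )
            aa = "A"
            if ancestral_known is not None and not ancestral_known[s]:
                aa = "a"
            rec.info["AA"] = aa
            for d in range(n_dip):
                rec.samples[f"sample{d}"]["GT"] = (
                    int(panel.alleles[2 * d, s]),
                    int(panel.alleles[2 * d + 1, s]),
                )
                rec.samples[f"sample{d}"].phased = True
            out.write(rec)


def save_panel_npz(panel: HaplotypePanel, path) -> None:
    """Native compressed array container with positions and map."""
    np.savez_compressed(
        path, alleles=panel.alleles, positions=panel.positions, map_cM=panel.map_cM
    )


def load_panel_npz(path) -> HaplotypePanel:
    with np.load(path) as data:
        return HaplotypePanel(data["alleles"], data["positions"], data["map_cM"])


def read_genetic_map(path) -> GeneticMap:
    """Read a genetic map, auto-detecting the dialect by header.

    HapMap style: whitespace table with a header line, a position column (bp)
    and a trailing cumulative map column (cM), e.g.
    ``position COMBINED_rate(cM/Mb) Genetic_Map(cM)``. PLINK style: four
    header-less columns ``chrom id cM bp``.
    """
    with open(path) as fh:
        first = fh.readline().split()

    def numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if first and not numeric(first[-1]):
        # header line (e.g. "position COMBINED_rate(cM/Mb) Genetic_Map(cM)")
        df = pd.read_csv(path, sep=r"\s+")
        pos_cols = [c for c in df.columns if "pos" in c.lower() or c.lower() == "bp"]
        pos_col = pos_cols[0] if pos_cols else df.columns[0]
        return GeneticMap(
            positions=df[pos_col].to_numpy(float),
            map_cM=df[df.columns[-1]].to_numpy(float),
        )
    if len(first) == 4:
        # header-less PLINK data: chrom id cM bp
        df = pd.read_csv(path, sep=r"\s+", header=None)
        return GeneticMap(positions=df[3].to_numpy(float), map_cM=df[2].to_numpy(float))
    if len(first) == 3 and all(numeric(t) for t in first):
        # header-less HapMap-style data: position rate cM
        df = pd.read_csv(path, sep=r"\s+", header=None)
        return GeneticMap(positions=df[0].to_numpy(float), map_cM=df[2].to_numpy(float))
    raise ValueError("unrecognized genetic map dialect")


def read_demography(path) -> DemographicModel:
    """Two-column whitespace table: generation (first row 0), diploid Ne."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError("demographic model file must have 2 columns")
    return DemographicModel(
        epochs=tuple(zip(df[0].to_numpy(float), df[1].to_numpy(float)))
    )


def write_segments_bed(
    path,
    piecewise: PiecewiseTmrca,
    track: TmrcaTrack,
    positions: np.ndarray,
    chrom: str = "1",
    pair_id: str = "0-1",
    append: bool = False,
) -> None:
    """BED-like TSV of piecewise TMRCA segments.

    Columns: chrom, start bp, end bp (0-based half-open, spanning from each
    boundary site's position), pair id, segment TMRCA, mean p_break.
    """
    rows = []
    for a, b, t in piecewise.segments:
        start = int(positions[a])
        end = int(positions[b]) if b < positions.size else int(positions[-1]) + 1
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "pair": pair_id,
                "tmrca": f"{t:.6g}",
                "mean_p_break": f"{float(track.p_break[a:b].mean()):.6g}",
            }
        )
    pd.DataFrame(rows).to_csv(
        path, sep="\t", index=False, header=not append, mode="a" if append else "w"
    )


def write_dating_tsv(path, estimates, panel: HaplotypePanel, sites, chrom: str = "1") -> None:
    """Per-variant dating output (1-based positions).

    ``estimates`` aligns with ``sites`` (panel site indices); variants that
    could not be dated should simply be absent.
    """
    dc = panel.derived_counts
    maf = panel.maf
    rows = []
    for est, s in zip(estimates, sites):
        rows.append(
            {
                "chrom": chrom,
                "pos": int(panel.positions[s]) + 1,
                "ref": "A",
                "alt": "G",
                "derived_allele": "G",
                "derived_count": int(dc[s]),
                "maf": f"{maf[s]:.6g}",
                "tc": "" if est.tc is None else f"{est.tc:.6g}",
                "td": "" if est.td is None else f"{est.td:.6g}",
                "age": f"{est.age:.6g}",
                "rejected_fraction": f"{est.rejected_fraction:.6g}",
                "n_concordant_kept": est.n_concordant_kept,
                "n_discordant_kept": est.n_discordant_kept,
                "flagged": int(est.flagged),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_annot(
    path,
    annotation: pd.DataFrame,
    positions: np.ndarray,
    map_cM: np.ndarray,
    chrom: str = "1",
    bin_edges: Optional[np.ndarray] = None,
) -> None:
    """S-LDSC .annot-style whitespace table (CHR, BP, SNP, CM, ANNOT) with a
    JSON sidecar recording the MAF bin edges."""
    idx = annotation["variant_index"].to_numpy(int)
    df = pd.DataFrame(
        {
            "CHR": chrom,
            "BP": positions[idx].astype(int) + 1,
            "SNP": [f"{chrom}:{int(p) + 1}" for p in positions[idx]],
            "CM": map_cM[idx],
            "ANNOT": annotation["normalized_age"].to_numpy(),
        }
    )
    df.to_csv(path, sep=" ", index=False)
    if bin_edges is not None:
        sidecar = Path(str(path) + ".bins.json")
        sidecar.write_text(json.dumps({"maf_bin_edges": list(map(float, bin_edges))}))
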