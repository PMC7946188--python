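"""Genome genetic map: autosome lengths and map-block assignment.

Genetic lengths are sex-averaged values for the 22 human autosomes in
centimorgans, totalling ~35.45 Morgans. All public functions accept an
optional custom map (dict of chromosome label -> length in cM) so that
reduced synthetic genomes can flow through the same code paths.
"""

from __future__ import annotations

import numpy as np

# Sex-averaged autosomal genetic lengths (cM).
DEFAULT_AUTOSOME_CM: dict[str, float] = {
    "1": 286.3, "2": 268.8, "3": 223.4, "4": 214.6, "5": 204.1,
    "6": 192.0, "7": 187.2, "8": 168.0, "9": 166.4, "10": 181.0,
    "11": 158.2, "12": 174.7, "13": 125.7, "14": 120.2, "15": 141.3,
    "16": 134.0, "17": 128.5, "18": 117.5, "19": 107.9, "20": 108.3,
    "21": 62.8, "22": 74.1,
}


def genome_map(custom: dict[str, float] | None = None) -> dict[str, float]:
    """Return a chromosome -> genetic length (cM) mapping.

    Defaults to the 22 human autosomes; any custom map must have strictly
    positive lengths.
    """
    gm = dict(custom) if custom is not None else dict(DEFAULT_AUTOSOME_CM)
    for chrom, length in gm.items():
        if not length > 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
    return gm


def total_morgans(gmap: dict[str, float]) -> float:
    return sum(gmap.values()) / 100.0


def map_blocks(
    chromosomes: np.ndarray, genetic_pos_m: np.ndarray, block_cm: float = 5.0
) -> np.ndarray:
    """Assign each SNP to a contiguous genetic-map block.

    Blocks are half-open intervals of ``block_cm`` centimorgans tiled from the
    start of each chromosome; block ids are globally unique integers, dense
    (0..n_blocks-1), and contiguous along the map. Used for block-jackknife
    standard errors robust to linkage.
    """
    if block_cm <= 0:
        raise ValueError("block_cm must be positive")
    chromosomes = np.asarray(chromosomes)
    pos_cm = np.asarray(genetic_pos_m, dtype=float) * 100.0
    block_ids = np.empty(len(chromosomes), dtype=np.int64)
    next_id = 0
    # preserve first-appearance chromosome order
    seen: dict[str, None] = {}
    for c in chromosomes:
        seen.setdefault(str(c), None)
    for chrom in seen:
        sel = chromosomes == chrom
        local = np.floor(pos_cm[sel] / block_cm).astype(np.int64)
        # densify within the chromosome so empty intervals don't make blocks
        uniq, inv = np.unique(local, return_inverse=True)
        block_ids[sel] = next_id + inv
        next_id += len(uniq)
    return block_ids
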