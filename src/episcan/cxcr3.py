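"""Embedded reference data for the human chemokine receptor CXCR3.

The 36-peptide array tiling CXCR3 isoform 1 (UniProt P49682, 368 aa) is the
canonical design this package was built around: consecutive 20-mers stepped
by 10 residues, the final tile truncated to an 18-mer so the C-terminus is
covered.  Each entry carries the physicochemical descriptors reported for
the synthesized (biotinylated) peptides: average molecular weight in Da,
Kyte-Doolittle GRAVY, isoelectric point, and net charge at pH 7.

The full receptor sequence is reconstructed from the overlapping tiles, so
no external FASTA download is needed.
"""

from __future__ import annotations

# index, sequence, start, end, MW (Da, biotinylated), GRAVY, pI, charge @ pH 7
PEPTIDE_TABLE: list[tuple[int, str, int, int, float, float, float, float]] = [
    (1, "MVLEVSDHQVLNDAEVAALL", 1, 20, 2392.3, 0.72, 3.74, -3.92),
    (2, "LNDAEVAALLENFSSSYDYG", 11, 30, 2441.0, -0.13, 3.30, -4.09),
    (3, "ENFSSSYDYGENESDSCCTS", 21, 40, 2486.8, -1.26, 3.23, -5.18),
    (4, "ENESDSCCTSPPCPQDFSLN", 31, 50, 2435.7, -0.96, 3.30, -4.23),
    (5, "PPCPQDFSLNFDRAFLPALY", 41, 60, 2536.5, -0.06, 4.11, -1.14),
    (6, "FDRAFLPALYSLLFLLGLLG", 51, 70, 2464.9, 1.50, 6.33, -0.09),
    (7, "SLLFLLGLLGNGAVAAVLLS", 61, 80, 2188.8, 2.04, 6.10, -0.09),
    (8, "NGAVAAVLLSRRTALSSTDT", 71, 90, 2228.4, 0.31, 10.40, 0.91),
    (9, "RRTALSSTDTFLLHLAVADT", 81, 100, 2413.6, 0.20, 7.55, 0.08),
    (10, "FLLHLAVADTLLVLTLPLWA", 91, 110, 2446.1, 1.82, 5.29, -0.92),
    (11, "LLVLTLPLWAVDAAVQWVFG", 101, 120, 2476.0, 1.63, 3.75, -1.09),
    (12, "VDAAVQWVFGSGLCKVAGAL", 111, 130, 2215.7, 1.16, 6.16, -0.14),
    (13, "SGLCKVAGALFNINFYAGAL", 121, 140, 2255.0, 1.06, 8.52, 0.86),
    (14, "FNINFYAGALLLACISFDRY", 131, 150, 2538.0, 0.90, 6.16, -0.14),
    (15, "LLACISFDRYLNIVHATQLY", 141, 160, 2579.6, 0.75, 7.35, 0.03),
    (16, "LNIVHATQLYRRGPPARVTL", 151, 170, 2500.9, -0.11, 12.20, 3.07),
    (17, "RRGPPARVTLTCLAVWGLCL", 161, 180, 2408.2, 0.62, 10.52, 2.81),
    (18, "TCLAVWGLCLLFALPDFIFL", 171, 190, 2501.5, 2.07, 3.75, -1.18),
    (19, "LFALPDFIFLSAHHDERLNA", 181, 200, 2551.7, 0.31, 5.36, -1.75),
    (20, "SAHHDERLNATHCQYNFPQV", 191, 210, 2592.7, -1.13, 6.78, -0.64),
    (21, "THCQYNFPQVGRTALRVLQL", 201, 220, 2571.2, -0.20, 9.50, 2.03),
    (22, "GRTALRVLQLVAGFLLPLLV", 211, 230, 2375.3, 1.50, 12.50, 1.91),
    (23, "VAGFLLPLLVMAYCYAHILA", 221, 240, 2404.6, 1.93, 7.35, 0.02),
    (24, "MAYCYAHILAVLLVSRGQRR", 231, 250, 2546.0, 0.51, 10.13, 3.02),
    (25, "VLLVSRGQRRLRAMRLVVVV", 241, 260, 2545.8, 0.85, 13.10, 4.91),
    (26, "LRAMRLVVVVVVAFALCWTP", 251, 270, 2471.0, 1.85, 10.53, 1.86),
    (27, "VVAFALCWTPYHLVVLVDIL", 261, 280, 2497.5, 1.92, 5.29, -0.97),
    (28, "YHLVVLVDILMDLGALARNC", 271, 290, 2454.4, 1.21, 5.41, -0.97),
    (29, "MDLGALARNCGRESRVDVAK", 281, 300, 2388.1, -0.36, 8.55, 0.86),
    (30, "GRESRVDVAKSVTSGLGYMH", 291, 310, 2374.9, -0.43, 9.30, 1.08),
    (31, "SVTSGLGYMHCCLNPLLYAF", 301, 320, 2415.2, 0.85, 7.25, -0.02),
    (32, "CCLNPLLYAFVGVKFRERMW", 311, 330, 2672.8, 0.50, 8.80, 1.81),
    (33, "VGVKFRERMWMLLLRLGCPN", 321, 340, 2644.2, 0.25, 11.38, 2.86),
    (34, "MLLLRLGCPNQRGLQRQPSS", 331, 350, 2492.9, -0.49, 12.20, 2.86),
    (35, "QRGLQRQPSSSRRDSSWSET", 341, 360, 2574.1, -2.01, 12.02, 1.91),
    (36, "SRRDSSWSETSEASYSGL", 351, 368, 2229.0, -1.27, 4.43, -1.09),
]

N_PEPTIDES = len(PEPTIDE_TABLE)


def _reconstruct_sequence() -> str:
    """Merge the overlapping tiles back into the 368-residue receptor."""
    seq = PEPTIDE_TABLE[0][1]
    for _, pep, start, _, *_ in PEPTIDE_TABLE[1:]:
        overlap = len(seq) - (start - 1)
        if seq[start - 1:] != pep[:overlap]:
            raise ValueError("tile overlap mismatch during reconstruction")
        seq += pep[overlap:]
    return seq


CXCR3_SEQUENCE: str = _reconstruct_sequence()
CXCR3_ID = "P49682"


def peptide_properties_frame():
    """The embedded array design as a DataFrame (one row per peptide)."""
    import pandas as pd

    return pd.DataFrame(
        PEPTIDE_TABLE,
        columns=["peptide", "sequence", "start", "end", "mw", "gravy", "pi", "charge"],
    ).set_index("peptide")
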