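"""Packaged reference panel of signal peptides.

The panel comprises 17 CHO-homologous elements (E1-E17), 15 literature-mined
elements (X1-X15), 5 synthetic elements from the initial library screen
(S1-S5), the industrial standard control "C" (murine Ig heavy-chain leader,
ISC) and 3 model-selected synthetic elements (NS1-NS3): 41 records in total.

X10 ("secrecon") is printed in its source with an ambiguous two-residue
suffix (``.../AA``); it is stored verbatim with ``ambiguous=True`` and two
concrete readings, and is excluded from any computation that requires a
single sequence unless explicitly resolved.
"""

from __future__ import annotations

from .records import Origin, SignalPeptideRecord

ISC_ID = "C"

_E = Origin.CHO_HOMOLOGOUS
_X = Origin.LITERATURE
_S = Origin.SYNTHETIC
_C = Origin.CONTROL

# id, sequence, origin, note
_PANEL: list[tuple[str, str, Origin, str]] = [
    ("E1", "MAPFASLASGILLLLSLITSSKA", _E, "TIMP1 signal peptide"),
    ("E2", "MLLGPGHTLSAPALALAVTLTLLVRSASP", _E, "CSPG4 signal peptide"),
    ("E3", "MLLSVPLLLGLLGLAAA", _E, "Calreticulin (CALR) signal peptide"),
    ("E4", "MQELRGILLCLLLAAAVPTTP", _E, "DKK3 signal peptide"),
    ("E5", "MRYVASYLLAALGGNS", _E, "RPLP2 N-terminus"),
    ("E6", "MGKSPEAWCIVLFSVLASFSA", _E, "Complement C1s signal peptide"),
    ("E7", "MASSGSVQQPRLVLLMLVLAGAARA", _E, "Cathepsin Z signal peptide"),
    ("E8", "MRWKIIQLQYCFLLVPCMLTALEA", _E, "Nucleobindin-2 signal peptide"),
    ("E9", "MLSRSLLCLALAWVARVGA", _E, "PDIA1 signal peptide"),
    ("E10", "MRFSCLALLPGVALLLASARLAAA", _E, "PDIA3 signal peptide"),
    ("E11", "MRVLWVLGLCCVLLTFGFVRA", _E, "Endoplasmin (HSP90B1) signal peptide"),
    ("E12", "MKFPMVAAALLLLCAVRA", _E, "BiP (HSPA5) signal peptide"),
    ("E13", "MRSLLLASFCLLAVALA", _E, "Serpinh1 signal peptide"),
    ("E14", "MKILLLCVGLLLTWDNGMVLG", _E, "Clusterin (CLU) signal peptide"),
    ("E15", "MLRISGRNMKVLFAAALIVGSVVFLLLPGPSVA", _E, "PPIB signal peptide"),
    ("E16", "MAATVRRQRPRRLLCWTLVAVLLADLLALS", _E, "HYOU1 signal peptide"),
    ("E17", "MKMGVRLAARAWPLCGLLLAALGGVCA", _E, "DDOST signal peptide"),
    ("X1", "MWWRLWWLLLLLLLLWLALAAAA", _X, "SSP1"),
    ("X2", "MGWSLILLFLVAVATRVLS", _X, "rituximab native HC"),
    ("X3", "MDFQVQIISFLLISASVIMSRG", _X, "rituximab native LC"),
    ("X4", "MEFGLSWVFLVALFRGVQC", _X, "H7"),
    ("X5", "MKWVTFISLLFLFSSAYS", _X, "serum albumin preproprotein (B)"),
    ("X6", "MKLPVRLLVLMFWIPAASA", _X, "ASA"),
    ("X7", "MNLLLILTFVAAAVA", _X, "human trypsinogen-2"),
    ("X8", "MGSAALLLWVLLLWVPSSRA", _X, "modified Ig kappa MOPC63-like (mIgk C)"),
    ("X9", "MTRLTVLALLAGLLASSRA", _X, "azurocidin preproprotein (E)"),
    ("X10", "MWWRLWWLLLLLLLLWPMVWA/AA", _X, "secrecon; ambiguous printed suffix"),
    ("X11", "MKLPVRLLVLMFWIPASSS", _X, "SSS"),
    ("X12", "MDMRVPAQLLGLLLLWLSGARC", _X, "L1"),
    ("X13", "MKYLLPTAAAGLLLLAAQPAMA", _X, "L2"),
    ("X14", "MGVKVLFALICIAVAEA", _X, "native Gaussia luciferase leader"),
    ("X15", "MPLLLLLPLLWAGALA", _X, "CD33"),
    ("S1", "MRARALLAVLLLLLLVGIAAAA", _S, "synthetic library screen"),
    ("S2", "MATATLLAVLLLLLLVGSAGGA", _S, "synthetic library screen"),
    ("S3", "MRARALLVVLVLVVLLGVASSA", _S, "synthetic library screen"),
    ("S4", "MPGPGAALLLLLLVLLGLGSAA", _S, "synthetic library screen"),
    ("S5", "MTTTTVLLLLVLVVLAGLTSGA", _S, "synthetic library screen"),
    ("C", "MGWSCIILFLVATATGVHS", _C, "murine Ig HC leader; industrial standard control (ISC)"),
    ("NS1", "MRKKTALVVLVLLLLAPIGASG", _S, "model-selected synthetic"),
    ("NS2", "MRKKTVLLVVLALLLAPIGASG", _S, "model-selected synthetic"),
    ("NS3", "MRKKTLLLLAVLVVVLPSTSSS", _S, "model-selected synthetic"),
]

#: Concrete readings of the ambiguous X10 suffix, in printed order.
X10_VARIANTS = ("MWWRLWWLLLLLLLLWPMVWA", "MWWRLWWLLLLLLLLWPMVAA")


def load_reference_panel(resolve_ambiguous: bool = False) -> list[SignalPeptideRecord]:
    """Return the packaged 41-record signal-peptide panel.

    With ``resolve_ambiguous=True`` the ambiguous X10 entry is replaced by its
    first concrete reading so every record has a computable sequence.
    """
    records = []
    for rid, seq, origin, note in _PANEL:
        ambiguous = "/" in seq
        if ambiguous and resolve_ambiguous:
            records.append(SignalPeptideRecord(rid, X10_VARIANTS[0], origin, note + " (resolved)"))
        else:
            records.append(SignalPeptideRecord(rid, seq, origin, note, ambiguous=ambiguous))
    return records


def single_chain_screen_panel(resolve_ambiguous: bool = True) -> list[SignalPeptideRecord]:
    """The 38 elements of the single-chain screens: the 37-part toolbox plus the ISC.

    Excludes the post-hoc model-selected NS elements.
    """
    return [r for r in load_reference_panel(resolve_ambiguous) if not r.id.startswith("NS")]
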