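"""Published study inputs consumed by the analyses.

``EXCHANGE_PANEL`` holds the measured fraction sum residuals (percent) for
the eight restriction-factor / Ty1c-CA pairings of the SEC-MALLS exchange
panel, together with the three-residue Dimer-1 interface motif of each
component (AVL: canonical Ty1c/p18; VTF: ancestral Ty1'/Drt2).  Pairs with
mismatched motifs do not exchange and define the scoring background.

``P18M_LIKE`` and ``DRT2M_LIKE`` collect the solution self-association
parameters reported for the two minimal restriction factors, used as
generating truth in closed-loop sedimentation-equilibrium simulations.
"""

from __future__ import annotations

from dimerswap.sedeq import AssociationModel

#: (CA label, restriction-factor label, theta_res %, CA motif, RF motif)
EXCHANGE_PANEL: list[tuple[str, str, float, str, str]] = [
    ("Ty1c CA(F323S)", "p18m(F323S)", 25.4, "AVL", "AVL"),
    ("Ty1c CA(F323S)", "Drt2m(SSS)", 2.7, "AVL", "VTF"),
    ("Ty1c CA(F323S)", "p18m-VTF(F323S)", 2.0, "AVL", "VTF"),
    ("Ty1c CA(F323S)", "Drt2m-AVL(SSS)", 6.2, "AVL", "AVL"),
    ("Ty1c CA-VTF(F323S)", "p18m(F323S)", 2.0, "VTF", "AVL"),
    ("Ty1c CA-VTF(F323S)", "Drt2m(SSS)", 3.2, "VTF", "VTF"),
    ("Ty1c CA-VTF(F323S)", "p18m-VTF(F323S)", 17.6, "VTF", "VTF"),
    ("Ty1c CA-VTF(F323S)", "Drt2m-AVL(SSS)", 2.3, "VTF", "AVL"),
]


def exchange_panel_records() -> list[tuple[str, str, float, bool]]:
    """Panel rows as (ca, rf, theta, is_background) scoring records."""
    return [
        (ca, rf, theta, motif_ca != motif_rf)
        for ca, rf, theta, motif_ca, motif_rf in EXCHANGE_PANEL
    ]


#: reported monomer-dimer / dimer-tetramer dissociation constants (M) and
#: the loading concentration (µM, monomer-equivalent) of the profiled cell
P18M_LIKE = {
    "model": AssociationModel(monomer_mass=11500.0, kd12=0.71e-6, kd24=30.5e-6),
    "loading_uM": 45.0,
}
DRT2M_LIKE = {
    "model": AssociationModel(monomer_mass=11500.0, kd12=0.48e-6, kd24=277e-6),
    "loading_uM": 44.0,
}

#: rotor speeds (rpm) and temperature (K) of the equilibrium experiments
AUC_SPEEDS = (20000.0, 23000.0, 26000.0)
AUC_TEMPERATURE = 293.0

#: Dimer-1 diagnostic positions in Ty1c Gag numbering and their fixed
#: residues in each subfamily
DIMER1_POSITIONS_AVL = {266: "A", 270: "V", 312: "L"}
DIMER1_POSITIONS_VTF = {266: "V", 270: "T", 312: "F"}
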