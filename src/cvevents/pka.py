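"""Default collective-variable set for the PKA RIα A-domain H→B transition.

Twenty-six observables covering the known steps of the cAMP-induced
transition of the A-domain (a.a. 118–241): the electrostatic switch
cAMP(O6)–A202(N-H)–G199(C=O), the PBC helix 3₁₀→α change, the
N3A-motif/PBC hydrophobic cluster (L135, F136, L203, I204), B/C-helix
rotation and its α→π→kink changes around a.a. 229–234, the L203–Y229
hydrophobic switch, the R209–D170–R226 relay, and segment RMSDs to the
cAMP-bound (B) conformation.  Each definition is swappable through the
pipeline configuration; this module only provides the defaults.

Residue numbering follows the RIα construct (a.a. 118–241); the cAMP
ligand is expected as residue name CMP with its equatorial exocyclic
oxygen named O6.
"""

from __future__ import annotations

from .cv import CVDefinition
from .structures import Structure

__all__ = ["default_cv_definitions", "DEFAULT_CV_IDS", "SEGMENTS"]

#: residue ranges of the structural elements used by segment CVs
SEGMENTS = {
    "pbc": (199, 211),
    "n3a": (119, 136),
    "bc_helix": (226, 241),
    "bc_turn": (229, 234),
    "pbc_short_helix": (196, 204),
    "domain": (118, 241),
    "beta_subdomain": (156, 198),
}


def default_cv_definitions(reference: Structure | None = None) -> list[CVDefinition]:
    """The default 26-CV set.

    ``reference`` is the B-conformation structure used by the segment-RMSD
    and helix-rotation CVs; when ``None``, those five CVs are omitted and the
    remaining 21 returned (useful for topologies without a reference).
    """
    sc = "and sidechain"
    defs = [
        CVDefinition(
            "d_A202N_cAMP_O6", "hbond_distance",
            ("resid 202 and name N", "resname CMP and name O6"), unit="Å",
        ),
        CVDefinition(
            "d_G199O_A202N", "hbond_distance",
            ("resid 199 and name O", "resid 202 and name N"), unit="Å",
        ),
        CVDefinition(
            "d_ca_L135_I204", "ca_distance",
            ("resid 135 and name CA", "resid 204 and name CA"), unit="Å",
        ),
        # hydrophobic cluster: N3A side chains against PBC side chains
        CVDefinition("d_sc_L135_L203", "centroid_distance",
                     (f"resid 135 {sc}", f"resid 203 {sc}"), unit="Å"),
        CVDefinition("d_sc_L135_I204", "centroid_distance",
                     (f"resid 135 {sc}", f"resid 204 {sc}"), unit="Å"),
        CVDefinition("d_sc_F136_L203", "centroid_distance",
                     (f"resid 136 {sc}", f"resid 203 {sc}"), unit="Å"),
        CVDefinition("d_sc_F136_I204", "centroid_distance",
                     (f"resid 136 {sc}", f"resid 204 {sc}"), unit="Å"),
        CVDefinition(
            "d_L203_pocket", "centroid_distance",
            (f"resid 203 {sc}", "resid 168-172 and backbone"), unit="Å",
        ),
    ]
    if reference is not None:
        defs += [
            CVDefinition("rmsd_pbc", "segment_rmsd", reference=reference,
                         params={"residue_range": SEGMENTS["pbc"]}, unit="Å"),
            CVDefinition("rmsd_n3a", "segment_rmsd", reference=reference,
                         params={"residue_range": SEGMENTS["n3a"]}, unit="Å"),
            CVDefinition("rmsd_bc_helix", "segment_rmsd", reference=reference,
                         params={"residue_range": SEGMENTS["bc_helix"]}, unit="Å"),
            CVDefinition("rmsd_domain", "segment_rmsd", reference=reference,
                         params={"residue_range": SEGMENTS["domain"]}, unit="Å"),
            CVDefinition(
                "angle_bc_helix", "helix_rotation", reference=reference,
                params={"helix_range": SEGMENTS["bc_helix"],
                        "anchor_range": SEGMENTS["beta_subdomain"]},
                unit="deg",
            ),
        ]
    defs += [
        CVDefinition("frac_310_bc_turn", "helix_form_fraction",
                     params={"residue_range": SEGMENTS["bc_turn"], "form": "three_ten"}),
        CVDefinition("frac_alpha_bc_turn", "helix_form_fraction",
                     params={"residue_range": SEGMENTS["bc_turn"], "form": "alpha"}),
        CVDefinition("frac_pi_bc_turn", "helix_form_fraction",
                     params={"residue_range": SEGMENTS["bc_turn"], "form": "pi"}),
        CVDefinition(
            "e_Y229_beta", "contact_energy",
            (f"resid 229 {sc}", f"resid 172,200,203,204 {sc}"), unit="kcal/mol",
        ),
        CVDefinition("d_Y229_L203", "centroid_distance",
                     (f"resid 229 {sc}", f"resid 203 {sc}"), unit="Å"),
        CVDefinition(
            "d_R241_E200", "centroid_distance",
            ("resid 241 and name NE,NH1,NH2", "resid 200 and name OE1,OE2"), unit="Å",
        ),
        CVDefinition("d_L238_I204", "centroid_distance",
                     (f"resid 238 {sc}", f"resid 204 {sc}"), unit="Å"),
        CVDefinition("d_L233_cluster", "centroid_distance",
                     (f"resid 233 {sc}", f"resid 135,136,139,172 {sc}"), unit="Å"),
        CVDefinition("d_M234_I204", "centroid_distance",
                     (f"resid 234 {sc}", f"resid 204 {sc}"), unit="Å"),
        CVDefinition("frac_alpha_pbc", "helix_form_fraction",
                     params={"residue_range": SEGMENTS["pbc_short_helix"], "form": "alpha"}),
        CVDefinition(
            "d_R209_D170", "centroid_distance",
            ("resid 209 and name NE,NH1,NH2", "resid 170 and name OD1,OD2"), unit="Å",
        ),
        CVDefinition(
            "d_R226_D170", "centroid_distance",
            ("resid 226 and name NE,NH1,NH2", "resid 170 and name OD1,OD2"), unit="Å",
        ),
        CVDefinition(
            "d_N3A_PBC", "centroid_distance",
            ("resid 119-136 and backbone", "resid 199-211 and backbone"), unit="Å",
        ),
    ]
    return defs


#: ids of the full 26-CV default set, in definition order
DEFAULT_CV_IDS = [
    "d_A202N_cAMP_O6", "d_G199O_A202N", "d_ca_L135_I204",
    "d_sc_L135_L203", "d_sc_L135_I204", "d_sc_F136_L203", "d_sc_F136_I204",
    "d_L203_pocket",
    "rmsd_pbc", "rmsd_n3a", "rmsd_bc_helix", "rmsd_domain", "angle_bc_helix",
    "frac_310_bc_turn", "frac_alpha_bc_turn", "frac_pi_bc_turn",
    "e_Y229_beta", "d_Y229_L203", "d_R241_E200", "d_L238_I204",
    "d_L233_cluster", "d_M234_I204", "frac_alpha_pbc",
    "d_R209_D170", "d_R226_D170", "d_N3A_PBC",
]
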