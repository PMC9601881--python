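name	start_residue	end_residue	note
activation_loop	504	530	activation loop; phosphorylation switches the kinase on
alphaC_beta4_loop	418	427	modulates the orientation of helix alphaC; hotspot for activating mutations
HRD_aspartate	486	486	catalytic aspartate of the conserved His-Arg-Asp motif
catalytic_loop_arginine	490	490	active-site arginine aligning reactants for catalysis
alphaC_beta4_methionine	426	426	top of the regulatory spine; acidic or proline substitutions activate
F_helix_aspartate	546	546	anchors the catalytic-loop backbone to the F helix
C_terminal_helix_leucine	616	616	surface-exposed leucine; hydrophilic substitutions boost soluble expression
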