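"""Generate the two benchmark families and check their planted structure.

The GN family has four equal communities of 32 with expected degree 16;
z_out controls how many of those edges leave the community.  The LFR
family has power-law degrees and community sizes; mu is the expected
fraction of each node's edges leaving its community.
"""

from mmgg import GNParams, LFRParams, generate_gn, generate_lfr, mixing_fraction

net, part = generate_gn(GNParams(z_out=8.0, seed=0))
print(
    f"GN  z_out=8 : {net.n_nodes} nodes, {net.n_edges} edges, "
    f"mean degree {net.degrees.mean():.2f}, "
    f"community sizes {part.sizes.tolist()}, "
    f"realized mixing {mixing_fraction(net, part):.3f}"
)

net, part = generate_lfr(LFRParams(n_nodes=1000, mu=0.75, seed=0))
print(
    f"LFR mu=0.75 : {net.n_nodes} nodes, {net.n_edges} edges, "
    f"{part.k} communities (sizes {part.sizes.min()}..{part.sizes.max()}), "
    f"realized mixing {mixing_fraction(net, part):.3f}"
)

# the realized mixing should sit within ~0.01 of the requested value,
# and LFR community sizes within the configured [10, 50] bounds.
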