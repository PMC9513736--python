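"""Why shadow compensation matters: FD% bias under a vessel shadow.

A homogeneous phantom (no lesion) carries one wide stripe where both the
angiogram and the structural image are attenuated by 50%, emulating the
shadow of a large superficial retinal vessel. Without compensation the local
threshold misreads the dimmed stripe and FD% inside it is biased by >10
percentage points; multiplying the angiogram by the inverted structural image
removes nearly all of the bias.
"""

from ccrings import PhantomSpec, compensate_angiogram, generate_phantom, phansalkar_threshold

spec = PhantomSpec(
    seed=5, mnv_radius_um=0.0, halo_width_um=0.0,
    vessel_count=1, vessel_width_um=600.0, shadow_strength=0.5,
)
angiogram, structural, truth = generate_phantom(spec)
stripe = truth.vessel_mask


def fd_in_out(image):
    deficit = phansalkar_threshold(image).deficit
    return 100.0 * deficit[stripe].mean(), 100.0 * deficit[~stripe].mean()


fd_in, fd_out = fd_in_out(angiogram)
print(f"uncompensated: FD% inside stripe {fd_in:.2f}, outside {fd_out:.2f} "
      f"(gap {abs(fd_in - fd_out):.2f} points)")
fd_in, fd_out = fd_in_out(compensate_angiogram(angiogram, structural))
print(f"compensated:   FD% inside stripe {fd_in:.2f}, outside {fd_out:.2f} "
      f"(gap {abs(fd_in - fd_out):.2f} points)")
print(f"designed deficit fraction everywhere: {100 * truth.background_fraction:.2f}%")
print()
print("The true deficit load is identical inside and outside the stripe, so")
print("any gap is measurement bias introduced by the shadow.")
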