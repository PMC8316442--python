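"""Assay arithmetic: TEER, fluorescence per cell, positive fractions,
elastic modulus from rheology."""

from jamscope import (
    FluorescenceRecord,
    RheologyInput,
    TeerConfig,
    fluorescence_per_cell,
    modulus_from_storage,
    normalize_teer,
    positive_fraction,
)

teer = normalize_teer([400.0, 450.0, 380.0], TeerConfig())
print(f"TEER replicates {teer.values} ohm*cm2; mean {teer.mean:.1f} ohm*cm2")

low = normalize_teer(60.0)
print(f"reading below blank -> {low.values[0]:.1f} ohm*cm2, flagged={low.flags[0]}")

rec = FluorescenceRecord(mean_gray_value=1250.0, n_cells=250, n_positive=60)
print(f"fluorescence per cell: {fluorescence_per_cell(rec):.2f}; "
      f"positive fraction: {positive_fraction(rec):.2f}")

gel = RheologyInput(g_prime=1.0, g_double_prime=0.05, poisson_ratio=0.5)
print(f"G' = {gel.g_prime} kPa -> E = {modulus_from_storage(gel):.1f} kPa "
      f"(incompressible rubber elasticity: E = 3 G')")
# (raw - 100 ohm) * 0.33 cm2 is the blank-and-area normalisation; readings
# below the blank stay negative and flagged rather than being clipped.
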