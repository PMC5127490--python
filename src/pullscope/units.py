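"""Physical constants and the reduced-unit conventions of the simulator.

The bundled coarse-grained simulator works in Lennard-Jones reduced units:
the depth of one native-contact well sets the energy scale (eps = 1), the
bead mass is 1, lengths are in nanometres and Boltzmann's constant is 1, so
reduced temperature is energy. A single display constant maps reduced
temperature to kelvin so calibrated temperatures can be quoted alongside
the kelvin values used by off-lattice force fields.
"""

#: Gas constant in kJ/(mol K), used by the two-state melting fit.
R_GAS = 8.314e-3

#: Default kelvin per reduced-temperature unit for display of toy-model
#: temperatures.  Chosen so that the bundled toy structure's folding
#: temperature (~1.1 in reduced units) maps near 158 K, the scale on which
#: one-bead-per-residue Go models of a ~100 residue beta protein melt.
KELVIN_PER_REDUCED_T = 144.0


def reduced_to_kelvin(t_reduced: float, scale: float = KELVIN_PER_REDUCED_T) -> float:
    """Map a reduced temperature to kelvin for display."""
    return t_reduced * scale


def kelvin_to_reduced(t_kelvin: float, scale: float = KELVIN_PER_REDUCED_T) -> float:
    """Map a kelvin temperature to reduced units."""
    return t_kelvin / scale
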