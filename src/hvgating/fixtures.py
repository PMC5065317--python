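"""Published measurement tables and fit parameters, recorded verbatim.

These values are read-only fixtures: the activation-threshold table for
the mutant panel and the figure-legend fit parameters used by the
printed-value verification and the correlation/slope analyses. Units:
mV, nS; SEM in mV; n = number of cells.
"""

from __future__ import annotations

from types import MappingProxyType

__all__ = ["TABLE2_VTHR", "LEGEND_FITS", "FIG3S2_SIMULATION"]

#: G_AQ activation threshold V_THR (mV), SEM (mV, None where not reported), n cells.
TABLE2_VTHR = MappingProxyType(
    {
        "WT": (7.0, None, 26),
        "N4R": (173.0, None, 4),
        "R1A": (63.0, None, 4),
        "R1H": (-25.0, 1.9, 20),
        "R1H-N4R": (-20.7, 2.2, 14),
        "D185A-R1H": (40.0, 1.9, 13),
        "D185H-R1H": (80.0, 3.8, 7),
    }
)

#: Printed fit parameters from figure legends, keyed by figure panel.
LEGEND_FITS = MappingProxyType(
    {
        # I_TAIL-V Boltzmann fits (leak-subtracted, normalized)
        "itail_boltzmann": MappingProxyType(
            {
                "R1H": {"v_half": 46.5, "dx": 22.6},
                "R1H-N4R": {"v_half": 26.3, "dx": 16.3},
            }
        ),
        # G_STEP-V Boltzmann fits of the SH conductance
        "gsh_boltzmann_free": {"g_max": 3.4, "v_half": -164.0, "dx": 35.4},
        "gsh_boltzmann_constrained": {"g_max": 4.6, "v_half": -189.0, "dx": 42.1},
        # G_STEP-V Boltzmann fit of the AQ conductance after leak subtraction
        "gaq_boltzmann": {"g_max": 22.2, "v_half": 29.4, "dx": 24.9},
        # derivative-Gaussian fits, AQ gating (positive-voltage windows)
        "gaq_vpeak": MappingProxyType(
            {
                "R1H": {"area": -20.8, "omega": 76.2, "v_peak": 23.3},
                "D185A-R1H": {"area": -22.9, "omega": 76.2, "v_peak": 98.9},
                "D185H-R1H": {"area": -13.3, "omega": 76.2, "v_peak": 144.3},
            }
        ),
        # derivative-Gaussian fits, SH gating (window -200 to +40 mV)
        "gsh_vpeak": MappingProxyType(
            {
                "R1H": {"area": 5.1, "omega": 143.8, "v_peak": -183.5},
                "R1H-N4R": {"area": 5.6, "omega": 155.5, "v_peak": -188.9},
                "D185A-R1H": {"area": 4.4, "omega": 155.5, "v_peak": -187.9},
                "D185H-R1H": {"area": 5.1, "omega": 155.5, "v_peak": -197.5},
            }
        ),
        # pH_o dependence in the blocked-AQ background
        "gsh_vpeak_by_ph": MappingProxyType({5.5: -157.4, 6.5: -197.6, 7.5: -245.7}),
        "gaq_vhalf_by_ph": MappingProxyType({5.5: 66.3, 6.5: 25.0, 7.5: -15.7}),
        "gaq_shared_dx_by_ph": 16.2,
        # leak conductance
        "g_leak": {"value": 1.5, "sem": 0.2},
        # printed pH-slope and correlation results
        "ph_slope_vpeak": -44.2,
        "ph_slope_vhalf": -41.0,
        "pearson_gaq": 0.99,
        "pearson_gsh": -0.84,
        # conductance ratios under the two SH maxima
        "ratio_primary": 4.8,
        "ratio_alternative": 6.5,
    }
)

#: Parameters of the published derivative-method validation simulation:
#: noiseless Boltzmann G-V curves whose midpoint shifts 40 mV per pH_o unit.
FIG3S2_SIMULATION = MappingProxyType(
    {
        "gaq": {
            "dx": 26.0,
            "by_ph": MappingProxyType({5.5: {"v_half": 60.0, "g_max": 1.0}, 6.5: {"v_half": 20.0, "g_max": 0.5}}),
        },
        "gsh": {
            "dx": 31.0,
            "by_ph": MappingProxyType({5.5: {"v_half": -140.0, "g_max": 1.0}, 6.5: {"v_half": -100.0, "g_max": 0.5}}),
        },
        "expected_slope_mv_per_ph": 40.0,
    }
)
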