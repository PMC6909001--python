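"""Shared numerical constants.

The artificial flux bound doubles as the big-M constant in every MILP so
that "unbounded" (a flux pinned at the artificial bound) has a single
meaning across the package.
"""

#: Default magnitude of the artificial flux bound, mmol/gDCW/hr.
BOUND = 1000.0

#: Big-M used in MILP reformulations (GapFind/GapFill coupling, KKT
#: complementarity). Identical to BOUND by design.
BIG_M = 1000.0

#: Minimum production rate for a metabolite to count as "producible"
#: (GapFind/GapFill epsilon).
EPS_PRODUCTION = 1e-3

#: Solver feasibility tolerance.
FEAS_TOL = 1e-9

#: Reporting tolerance: fluxes within this of a value are that value.
REPORT_TOL = 1e-6

#: Fraction of BOUND at which a closed-exchange FVA flux counts as
#: unbounded (solver round-off near the artificial bound).
UNBOUNDED_FRACTION = 0.999
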