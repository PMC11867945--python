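# Packaged default parameter set for the Huzhou colorectal-cancer screening
# cost-effectiveness model.  Flat keys match crcscreen.parameters.ParameterSet
# field names.  Ranges are 95% intervals used for Beta/Gamma fitting in
# sensitivity analyses; family "fixed" parameters are never sampled.

# -- status distribution -----------------------------------------------------
p_high:        {value: 0.203,   low: 0.163,   high: 0.243,   family: beta}
p_low:         {value: 0.797,   low: 0.641,   high: 0.953,   family: beta}
prev_general:  {value: 0.0099,  low: 0.0080,  high: 0.0118,  family: beta}
prev_low:      {value: 0.0055,  low: 0.0046,  high: 0.0066,  family: beta}
prev_high:     {value: 0.027,   low: 0.0217,  high: 0.0323,  family: beta}

# -- utilities ---------------------------------------------------------------
u_health:      {value: 1.0,     family: fixed}
u_death:       {value: 0.0,     family: fixed}
u_early:       {value: 0.83,    low: 0.747,   high: 0.913,   family: beta}
u_adv_nomet:   {value: 0.66,    low: 0.594,   high: 0.726,   family: beta}
u_adv_met:     {value: 0.54,    low: 0.486,   high: 0.594,   family: beta}
u_screen:      {value: 0.85,    low: 0.68,    high: 0.91,    family: beta}
u_self:        {value: 0.74,    low: 0.60,    high: 0.89,    family: beta}

# per-stage EQ-5D-5L index scores, stages I-IV
eq5d_stage:    [0.893, 0.821, 0.698, 0.637]

# -- costs (USD per subject) -------------------------------------------------
c_fit:         {value: 5,       low: 4,       high: 6,       family: gamma}
c_colo:        {value: 195,     low: 157,     high: 233,     family: gamma}
c_early:       {value: 3249,    low: 2612,    high: 3886,    family: gamma}
c_adv_nomet:   {value: 7892,    low: 6346,    high: 9439,    family: gamma}
c_adv_met:     {value: 14034,   low: 11283,   high: 16784,   family: gamma}
c_hosp_adv:    {value: 1751,    family: fixed}
c_adjuvant:    {value: 1024,    family: fixed}
wage:          {value: 37,      low: 30,      high: 45,      family: gamma}
c_screen_crc:  {value: 6286,    low: 6118,    high: 9062,    family: gamma}
c_self_crc:    {value: 11672,   low: 11306,   high: 16748,   family: gamma}

n_adjuvant_nomet: 6
n_adjuvant_met:   12
days_early:       11.7
days_hosp_adv:    11.8
days_adjuvant:    3.6

# -- cure rates (10-year survival == cure) ------------------------------------
cure_early:     {value: 0.84,  low: 0.756,  high: 0.924,  family: beta}
cure_adv_nomet: {value: 0.64,  low: 0.576,  high: 0.704,  family: beta}
cure_adv_met:   {value: 0.09,  low: 0.081,  high: 0.099,  family: beta}
cure_screen:    {value: 0.77,  low: 0.62,   high: 0.92,   family: beta}
cure_self:      {value: 0.54,  low: 0.43,   high: 0.65,   family: beta}

# 10-year survival by stage I-IV
surv10_stage:   [0.838, 0.701, 0.573, 0.087]

# cumulative CRC death fractions at years 1, 3, 5, 10 after diagnosis
cumdeath_screen: [0.024, 0.078, 0.131, 0.231]
cumdeath_self:   [0.092, 0.249, 0.348, 0.464]

# -- incidence ----------------------------------------------------------------
inc_general:       {value: 0.002,   low: 0.0016,  high: 0.0024,  family: beta}
inc_postcolo_0_5:  {value: 0.0002,  low: 0.00012, high: 0.00023, family: beta}
inc_postcolo_5_10: {value: 0.00035, low: 0.00021, high: 0.00041, family: beta}

# -- other ---------------------------------------------------------------------
sens_primary:  {value: 0.83,    low: 0.65,    high: 0.95,    family: beta}
# printed range for the discount rate is inconsistent with its value; the
# pharmacoeconomic-guideline sensitivity span 0-8% is used instead
discount:      {value: 0.05,    low: 0.00,    high: 0.08,    family: beta}
mort_bg:       {value: 0.0063,  low: 0.0051,  high: 0.0075,  family: beta}
gdp:           {value: 17324,   low: 14096,   high: 20881,   family: gamma}

# -- stage mixes (early, advanced w/o metastasis, advanced w/ metastasis) ------
mix_screen:    [0.655, 0.345, 0.0]
# self-referred: 4.3% early, 95.7% advanced of which 20% metastatic
mix_self:      [0.043, 0.7656, 0.1914]

population:    804180
horizon:       10
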