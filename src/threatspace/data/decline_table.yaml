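# Expected percentage population decline (over a 10-year period or three
# generations) implied by an IUCN threat scope x severity combination.
#
# Cell values are constructed as round(scope-fraction midpoint x severity
# decline-rate midpoint): scope midpoints 0.95 / 0.70 / 0.25 for Whole /
# Majority / Minority; severity rate midpoints 40 (very rapid), 25 (rapid),
# 10 (slow significant), 8 (fluctuations), ~1 (negligible), 0 (none).
# Anchors asserted at load: (Whole, rapid declines) = 24; negligible or no
# decline over a majority or minority of the range = 0.  Values are
# monotone non-decreasing in scope for every severity (asserted at load);
# the abatement-scenario ordering relies on this.
#
# "Unknown" scope or severity is deliberately absent: records carrying
# unknown levels must be imputed or resolved upstream before scoring.
decline:
  "Whole (>90%)":
    "very rapid declines": 38
    "rapid declines": 24
    "slow significant declines": 10
    "causing/could cause fluctuations": 8
    "negligible declines": 1
    "no decline": 0
  "Majority (50-90%)":
    "very rapid declines": 28
    "rapid declines": 18
    "slow significant declines": 7
    "causing/could cause fluctuations": 6
    "negligible declines": 0
    "no decline": 0
  "Minority (<50%)":
    "very rapid declines": 10
    "rapid declines": 6
    "slow significant declines": 3
    "causing/could cause fluctuations": 2
    "negligible declines": 0
    "no decline": 0

# First-order (level-1) IUCN threat class -> driver-of-extinction label.
# Membership is an assumption (the natural reading of the six driver names
# against the IUCN level-1 classification); edit to override.
driver_map:
  "1": habitat loss and degradation    # residential & commercial development
  "2": habitat loss and degradation    # agriculture & aquaculture
  "3": habitat loss and degradation    # energy production & mining
  "4": disturbance and accidental mortality   # transportation & service corridors
  "5": hunting and collection          # biological resource use
  "6": disturbance and accidental mortality   # human intrusions & disturbance
  "7": habitat loss and degradation    # natural system modifications
  "8": invasive species and disease    # invasive & problematic species/disease
  "9": pollution
  "10": other                          # geological events
  "11": climate change and severe weather
  "12": other

# Threat columns affecting this many species or fewer are grouped.
rare_threshold: 10
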