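# Named teicoplanin regimens (30-min infusions).
# smpc_6mgkg: label regimen, 6 mg/kg q12h x3 loading then 6 mg/kg once daily.
# local_600: fixed-dose protocol, 600 mg q12h x3 loading then 600 mg once daily.
# intensified_12mgkg: 12 mg/kg q12h x5 loading then 12 mg/kg once daily.
# intensified_12mgkg_q12maint: exploratory variant keeping q12h maintenance
#   (for high-IBW subjects where once-daily maintenance is insufficient).

smpc_6mgkg:
  loading_dose: 6.0
  loading_basis: per_kg
  loading_count: 3
  loading_interval: 12.0
  maintenance_dose: 6.0
  maintenance_basis: per_kg
  maintenance_interval: 24.0

local_600:
  loading_dose: 600.0
  loading_basis: fixed
  loading_count: 3
  loading_interval: 12.0
  maintenance_dose: 600.0
  maintenance_basis: fixed
  maintenance_interval: 24.0

intensified_12mgkg:
  loading_dose: 12.0
  loading_basis: per_kg
  loading_count: 5
  loading_interval: 12.0
  maintenance_dose: 12.0
  maintenance_basis: per_kg
  maintenance_interval: 24.0

intensified_12mgkg_q12maint:
  loading_dose: 12.0
  loading_basis: per_kg
  loading_count: 5
  loading_interval: 12.0
  maintenance_dose: 12.0
  maintenance_basis: per_kg
  maintenance_interval: 12.0
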