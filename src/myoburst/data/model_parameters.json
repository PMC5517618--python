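{
  "description": "Full constant set of the mouse (apical) ventricular myocyte model. Units: ms, mV, pA/pF, mS/uF; Ca in uM, Na/K in mM; volumes in uL, Acap in cm^2, Cm in uF/cm^2. 'tg_overrides' lists the seven parameters that differ between wild-type (WT) and TNF-alpha overexpressing transgenic (TG) cells.",
  "constants": {
    "F": 96.5,
    "TEMP": 298.0,
    "RGAS": 8.314,
    "Acap": 1.534e-4,
    "Cm": 1.0,
    "Vmyo": 25.84e-6,
    "VJSR": 0.12e-6,
    "VNSR": 2.098e-6,
    "Vss": 1.485e-9,
    "Ko": 5.4,
    "Nao": 140.0,
    "Cao": 1800.0,
    "LTRPN_tot": 70.0,
    "HTRPN_tot": 140.0,
    "kp_htrpn": 0.00237,
    "km_htrpn": 3.2e-5,
    "kp_ltrpn": 0.0327,
    "km_ltrpn": 0.0196,
    "CMDN_tot": 50.0,
    "CSQN_tot": 15000.0,
    "Km_CMDN": 0.238,
    "Km_CSQN": 800.0,
    "v1": 4.5,
    "v2": 1.74e-5,
    "v3": 0.45,
    "Km_up": 0.5,
    "tau_tr": 20.0,
    "tau_xfer": 8.0,
    "kap_ryr": 0.006075,
    "kam_ryr": 0.07125,
    "kbp_ryr": 0.00405,
    "kbm_ryr": 0.965,
    "kcp_ryr": 0.009,
    "kcm_ryr": 0.0008,
    "GCaL": 0.1729,
    "ECaL": 63.0,
    "Kpc_max": 0.23324,
    "Kpc_half": 20.0,
    "Kpcb": 0.0005,
    "ICaL_max": 7.0,
    "GNa": 13.0,
    "GNab": 0.0026,
    "GCab": 0.000367,
    "kNaCa": 292.8,
    "Km_Na": 87.5,
    "Km_Ca": 1380.0,
    "k_sat": 0.1,
    "eta": 0.35,
    "IpCa_max": 1.0,
    "Km_pCa": 0.5,
    "INaK_max": 0.88,
    "Km_Nai": 21.0,
    "Km_Ko": 1.5,
    "GClCa": 10.0,
    "Km_Cl": 10.0,
    "ECl": -40.0,
    "GKtof": 0.4067,
    "GKtos": 0.0,
    "GKur": 0.16,
    "GKss": 0.05,
    "GKr": 0.078,
    "GKs": 0.00575,
    "GK1": 0.2938,
    "Km_K1": 0.21,
    "k1_power": 1.0,
    "k1_slope": 0.0896
  },
  "tg_overrides": {
    "v3": 0.36,
    "kNaCa": 442.0,
    "GKtof": 0.2847,
    "GKur": 0.12,
    "GK1": 0.22,
    "k1_power": 1.15,
    "k1_slope": 0.0837
  },
  "seven_parameters": ["v3", "kNaCa", "GKtof", "GKur", "GK1", "k1_power", "k1_slope"],
  "ina_scheme": {
    "states": ["C3", "C2", "C1", "O", "IF", "I1", "I2", "IC2", "IC3"],
    "edges": [
      ["C3", "C2", "a11"], ["C2", "C3", "b11"],
      ["C2", "C1", "a12"], ["C1", "C2", "b12"],
      ["C1", "O", "a13"], ["O", "C1", "b13"],
      ["O", "IF", "a2"], ["IF", "O", "b2"],
      ["IF", "C1", "a3"], ["C1", "IF", "b3"],
      ["IF", "I1", "a4"], ["I1", "IF", "b4"],
      ["I1", "I2", "a5"], ["I2", "I1", "b5"],
      ["IC2", "IF", "a12"], ["IF", "IC2", "b12"],
      ["IC3", "IC2", "a11"], ["IC2", "IC3", "b11"],
      ["IC2", "C2", "a3"], ["C2", "IC2", "b3"],
      ["IC3", "C3", "a3"], ["C3", "IC3", "b3"]
    ],
    "slow_inactivation_states": ["I1", "I2"]
  }
}
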