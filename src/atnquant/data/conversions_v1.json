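{
 "version": "v1",
 "amyloid": {
  "PiB": {
   "slope": 107.3768,
   "intercept": -103.7152,
   "r2": null
  },
  "FBP": {
   "slope": 194.8721,
   "intercept": -191.8315,
   "r2": 0.92
  },
  "FBB": {
   "slope": 165.2828,
   "intercept": -158.0409,
   "r2": 0.97
  },
  "FTM": {
   "slope": 141.1563,
   "intercept": -128.3451,
   "r2": 0.95
  },
  "NAV": {
   "slope": 104.8498,
   "intercept": -102.6445,
   "r2": 0.99
  }
 },
 "tau": {
  "FTP": {
   "slope": 16.937,
   "intercept": -19.1334,
   "r2": 0.98
  },
  "RO": {
   "slope": 17.2116,
   "intercept": -20.0144,
   "r2": null
  },
  "MK": {
   "slope": 12.2417,
   "intercept": -12.7801,
   "r2": null
  },
  "GTP": {
   "slope": 12.5556,
   "intercept": -13.8899,
   "r2": null
  },
  "PBB3": {
   "slope": 15.4067,
   "intercept": -14.6334,
   "r2": null
  },
  "PI": {
   "slope": 10.1753,
   "intercept": -11.5909,
   "r2": null
  }
 }
}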