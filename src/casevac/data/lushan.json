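{
 "schema_version": 1,
 "name": "lushan",
 "areas": [
  "I1",
  "I2",
  "I3",
  "I4",
  "I5",
  "I6",
  "I7",
  "I8",
  "I9"
 ],
 "temp_hospitals": [
  "J1",
  "J2",
  "J3",
  "J4",
  "J5"
 ],
 "general_hospitals": [
  "K1",
  "K2",
  "K3"
 ],
 "casualties": [
  {
   "area": "I1",
   "severity": "serious",
   "count": 59
  },
  {
   "area": "I2",
   "severity": "serious",
   "count": 21
  },
  {
   "area": "I3",
   "severity": "serious",
   "count": 23
  },
  {
   "area": "I4",
   "severity": "serious",
   "count": 29
  },
  {
   "area": "I5",
   "severity": "serious",
   "count": 20
  },
  {
   "area": "I6",
   "severity": "serious",
   "count": 70
  },
  {
   "area": "I7",
   "severity": "serious",
   "count": 12
  },
  {
   "area": "I8",
   "severity": "serious",
   "count": 16
  },
  {
   "area": "I9",
   "severity": "serious",
   "count": 5
  },
  {
   "area": "I1",
   "severity": "moderate",
   "count": 143
  },
  {
   "area": "I2",
   "severity": "moderate",
   "count": 48
  },
  {
   "area": "I3",
   "severity": "moderate",
   "count": 71
  },
  {
   "area": "I4",
   "severity": "moderate",
   "count": 116
  },
  {
   "area": "I5",
   "severity": "moderate",
   "count": 59
  },
  {
   "area": "I6",
   "severity": "moderate",
   "count": 153
  },
  {
   "area": "I7",
   "severity": "moderate",
   "count": 46
  },
  {
   "area": "I8",
   "severity": "moderate",
   "count": 71
  },
  {
   "area": "I9",
   "severity": "moderate",
   "count": 23
  }
 ],
 "road_times": [
  {
   "from": "I1",
   "to": "J1",
   "hours": 1.25
  },
  {
   "from": "I1",
   "to": "J2",
   "hours": 0.8
  },
  {
   "from": "I1",
   "to": "J3",
   "hours": 1.2
  },
  {
   "from": "I1",
   "to": "J4",
   "hours": 0.95
  },
  {
   "from": "I1",
   "to": "J5",
   "hours": 0.875
  },
  {
   "from": "I2",
   "to": "J1",
   "hours": 0.575
  },
  {
   "from": "I2",
   "to": "J2",
   "hours": 0.525
  },
  {
   "from": "I2",
   "to": "J3",
   "hours": 0.65
  },
  {
   "from": "I2",
   "to": "J4",
   "hours": 0.525
  },
  {
   "from": "I2",
   "to": "J5",
   "hours": 0.45
  },
  {
   "from": "I3",
   "to": "J1",
   "hours": 1.025
  },
  {
   "from": "I3",
   "to": "J2",
   "hours": 0.825
  },
  {
   "from": "I3",
   "to": "J3",
   "hours": 1.1
  },
  {
   "from": "I3",
   "to": "J4",
   "hours": 0.975
  },
  {
   "from": "I3",
   "to": "J5",
   "hours": 0.775
  },
  {
   "from": "I4",
   "to": "J1",
   "hours": 1.325
  },
  {
   "from": "I4",
   "to": "J2",
   "hours": 0.975
  },
  {
   "from": "I4",
   "to": "J3",
   "hours": 1.375
  },
  {
   "from": "I4",
   "to": "J4",
   "hours": 1.125
  },
  {
   "from": "I4",
   "to": "J5",
   "hours": 1.05
  },
  {
   "from": "I5",
   "to": "J1",
   "hours": 1.475
  },
  {
   "from": "I5",
   "to": "J2",
   "hours": 1.125
  },
  {
   "from": "I5",
   "to": "J3",
   "hours": 1.525
  },
  {
   "from": "I5",
   "to": "J4",
   "hours": 1.3
  },
  {
   "from": "I5",
   "to": "J5",
   "hours": 1.2
  },
  {
   "from": "I6",
   "to": "J1",
   "hours": 1.525
  },
  {
   "from": "I6",
   "to": "J2",
   "hours": 1.175
  },
  {
   "from": "I6",
   "to": "J3",
   "hours": 1.575
  },
  {
   "from": "I6",
   "to": "J4",
   "hours": 1.35
  },
  {
   "from": "I6",
   "to": "J5",
   "hours": 1.25
  },
  {
   "from": "I7",
   "to": "J1",
   "hours": 1.75
  },
  {
   "from": "I7",
   "to": "J2",
   "hours": 1.375
  },
  {
   "from": "I7",
   "to": "J3",
   "hours": 1.675
  },
  {
   "from": "I7",
   "to": "J4",
   "hours": 1.55
  },
  {
   "from": "I7",
   "to": "J5",
   "hours": 1.45
  },
  {
   "from": "I8",
   "to": "J1",
   "hours": 1.725
  },
  {
   "from": "I8",
   "to": "J2",
   "hours": 1.525
  },
  {
   "from": "I8",
   "to": "J3",
   "hours": 1.875
  },
  {
   "from": "I8",
   "to": "J4",
   "hours": 1.825
  },
  {
   "from": "I8",
   "to": "J5",
   "hours": 1.6
  },
  {
   "from": "I9",
   "to": "J1",
   "hours": 2.45
  },
  {
   "from": "I9",
   "to": "J2",
   "hours": 2.25
  },
  {
   "from": "I9",
   "to": "J3",
   "hours": 2.45
  },
  {
   "from": "I9",
   "to": "J4",
   "hours": 2.4
  },
  {
   "from": "I9",
   "to": "J5",
   "hours": 2.325
  }
 ],
 "air_times": [
  {
   "from": "J1",
   "to": "K1",
   "hours": 0.57
  },
  {
   "from": "J1",
   "to": "K2",
   "hours": 0.71
  },
  {
   "from": "J1",
   "to": "K3",
   "hours": 0.59
  },
  {
   "from": "J2",
   "to": "K1",
   "hours": 0.63
  },
  {
   "from": "J2",
   "to": "K2",
   "hours": 0.73
  },
  {
   "from": "J2",
   "to": "K3",
   "hours": 0.61
  },
  {
   "from": "J3",
   "to": "K1",
   "hours": 0.57
  },
  {
   "from": "J3",
   "to": "K2",
   "hours": 0.71
  },
  {
   "from": "J3",
   "to": "K3",
   "hours": 0.59
  },
  {
   "from": "J4",
   "to": "K1",
   "hours": 0.6
  },
  {
   "from": "J4",
   "to": "K2",
   "hours": 0.7
  },
  {
   "from": "J4",
   "to": "K3",
   "hours": 0.58
  },
  {
   "from": "J5",
   "to": "K1",
   "hours": 0.58
  },
  {
   "from": "J5",
   "to": "K2",
   "hours": 0.71
  },
  {
   "from": "J5",
   "to": "K3",
   "hours": 0.59
  }
 ],
 "fleet": {
  "n_vehicles": 280,
  "n_helicopters": 150,
  "vehicle_capacity": 6,
  "helicopter_capacity": 12
 },
 "capacities": {
  "temporary": {
   "J1": 500,
   "J2": 500,
   "J3": 500,
   "J4": 500,
   "J5": 500
  },
  "general": [
   {
    "hospital": "K1",
    "severity": "serious",
    "capacity": 250
   },
   {
    "hospital": "K1",
    "severity": "moderate",
    "capacity": 350
   },
   {
    "hospital": "K2",
    "severity": "serious",
    "capacity": 200
   },
   {
    "hospital": "K2",
    "severity": "moderate",
    "capacity": 300
   },
   {
    "hospital": "K3",
    "severity": "serious",
    "capacity": 200
   },
   {
    "hospital": "K3",
    "severity": "moderate",
    "capacity": 500
   }
  ]
 },
 "severity_params": {
  "serious": {
   "urgency_weight": 2,
   "base_deterioration": 0.8
  },
  "moderate": {
   "urgency_weight": 1,
   "base_deterioration": 0.2
  }
 },
 "post_treatment_factor": 0.2
}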