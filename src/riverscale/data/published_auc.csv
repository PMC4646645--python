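species,distance_m,varset,topo,auc,converged
Anguilla,0,MV,no,0.61,True
Anguilla,0,AV,no,0.68,True
Anguilla,200,MV,no,0.63,True
Anguilla,200,AV,no,0.75,True
Anguilla,1000,MV,no,0.81,True
Anguilla,1000,AV,no,0.83,True
Anguilla,2500,MV,no,0.76,True
Anguilla,2500,AV,no,0.82,True
Anguilla,4000,MV,no,0.73,True
Anguilla,4000,AV,no,0.82,True
Cobienia,0,MV,no,0.65,True
Cobienia,0,AV,no,0.75,True
Cobienia,200,MV,no,0.69,True
Cobienia,200,AV,no,0.69,True
Cobienia,1000,MV,no,0.69,True
Cobienia,1000,AV,no,0.78,True
Cobienia,2500,MV,no,0.66,True
Cobienia,2500,AV,no,0.82,True
Cobienia,4000,MV,no,0.78,True
Cobienia,4000,AV,no,0.79,True
Gastatus,0,MV,no,0.72,True
Gastatus,0,AV,no,,False
Gastatus,200,MV,no,0.78,True
Gastatus,200,AV,no,0.70,True
Gastatus,1000,MV,no,0.81,True
Gastatus,1000,AV,no,0.73,True
Gastatus,2500,MV,no,0.75,True
Gastatus,2500,AV,no,0.90,True
Gastatus,4000,MV,no,0.76,True
Gastatus,4000,AV,no,0.83,True
Gobiobio,0,MV,no,0.94,True
Gobiobio,0,AV,no,0.75,True
Gobiobio,200,MV,no,0.94,True
Gobiobio,200,AV,no,0.74,True
Gobiobio,1000,MV,no,0.96,True
Gobiobio,1000,AV,no,0.90,True
Gobiobio,2500,MV,no,0.97,True
Gobiobio,2500,AV,no,0.84,True
Gobiobio,4000,MV,no,0.88,True
Gobiobio,4000,AV,no,0.86,True
Gymnrnua,0,MV,no,0.68,True
Gymnrnua,0,AV,no,0.79,True
Gymnrnua,200,MV,no,0.72,True
Gymnrnua,200,AV,no,0.83,True
Gymnrnua,1000,MV,no,0.69,True
Gymnrnua,1000,AV,no,0.72,True
Gymnrnua,2500,MV,no,0.78,True
Gymnrnua,2500,AV,no,0.82,True
Gymnrnua,4000,MV,no,0.92,True
Gymnrnua,4000,AV,no,0.75,True
Leucscus,0,MV,no,0.78,True
Leucscus,0,AV,no,0.72,True
Leucscus,200,MV,no,0.68,True
Leucscus,200,AV,no,0.75,True
Leucscus,1000,MV,no,0.83,True
Leucscus,1000,AV,no,0.73,True
Leucscus,2500,MV,no,0.75,True
Leucscus,2500,AV,no,0.75,True
Leucscus,4000,MV,no,0.65,True
Leucscus,4000,AV,no,0.76,True
Percilis,0,MV,no,0.80,True
Percilis,0,AV,no,0.80,True
Percilis,200,MV,no,0.90,True
Percilis,200,AV,no,0.83,True
Percilis,1000,MV,no,0.78,True
Percilis,1000,AV,no,0.76,True
Percilis,2500,MV,no,0.93,True
Percilis,2500,AV,no,0.85,True
Percilis,4000,MV,no,0.85,True
Percilis,4000,AV,no,0.88,True
Phoxinus,0,MV,no,0.73,True
Phoxinus,0,AV,no,0.74,True
Phoxinus,200,MV,no,0.83,True
Phoxinus,200,AV,no,0.88,True
Phoxinus,1000,MV,no,0.89,True
Phoxinus,1000,AV,no,0.83,True
Phoxinus,2500,MV,no,0.87,True
Phoxinus,2500,AV,no,0.91,True
Phoxinus,4000,MV,no,0.88,True
Phoxinus,4000,AV,no,0.84,True
Pungtius,0,MV,no,0.72,True
Pungtius,0,AV,no,0.71,True
Pungtius,200,MV,no,0.69,True
Pungtius,200,AV,no,0.77,True
Pungtius,1000,MV,no,0.72,True
Pungtius,1000,AV,no,0.68,True
Pungtius,2500,MV,no,0.67,True
Pungtius,2500,AV,no,0.78,True
Pungtius,4000,MV,no,0.62,True
Pungtius,4000,AV,no,0.74,True
Rutiilus,0,MV,no,0.69,True
Rutiilus,0,AV,no,0.72,True
Rutiilus,200,MV,no,0.69,True
Rutiilus,200,AV,no,0.75,True
Rutiilus,1000,MV,no,0.70,True
Rutiilus,1000,AV,no,0.66,True
Rutiilus,2500,MV,no,0.74,True
Rutiilus,2500,AV,no,0.71,True
Rutiilus,4000,MV,no,0.73,True
Rutiilus,4000,AV,no,0.67,True
Salmalar,0,MV,no,0.88,True
Salmalar,0,AV,no,0.85,True
Salmalar,200,MV,no,0.87,True
Salmalar,200,AV,no,0.83,True
Salmalar,1000,MV,no,0.92,True
Salmalar,1000,AV,no,0.92,True
Salmalar,2500,MV,no,0.88,True
Salmalar,2500,AV,no,0.89,True
Salmalar,4000,MV,no,0.92,True
Salmalar,4000,AV,no,0.89,True
Salmario,0,MV,no,0.74,True
Salmario,0,AV,no,0.70,True
Salmario,200,MV,no,0.83,True
Salmario,200,AV,no,0.65,True
Salmario,1000,MV,no,0.90,True
Salmario,1000,AV,no,0.71,True
Salmario,2500,MV,no,0.76,True
Salmario,2500,AV,no,0.54,True
Salmario,4000,MV,no,0.88,True
Salmario,4000,AV,no,0.66,True
Tincinca,0,MV,no,0.76,True
Tincinca,0,AV,no,0.72,True
Tincinca,200,MV,no,0.67,True
Tincinca,200,AV,no,0.61,True
Tincinca,1000,MV,no,0.53,True
Tincinca,1000,AV,no,0.86,True
Tincinca,2500,MV,no,,False
Tincinca,2500,AV,no,0.75,True
Tincinca,4000,MV,no,0.78,True
Tincinca,4000,AV,no,0.75,True
Anguilla,0,MV,yes,0.72,True
Anguilla,0,AV,yes,0.81,True
Anguilla,200,MV,yes,0.66,True
Anguilla,200,AV,yes,0.80,True
Anguilla,1000,MV,yes,0.73,True
Anguilla,1000,AV,yes,0.87,True
Anguilla,2500,MV,yes,0.77,True
Anguilla,2500,AV,yes,0.90,True
Anguilla,4000,MV,yes,0.87,True
Anguilla,4000,AV,yes,0.76,True
Cobienia,0,MV,yes,0.69,True
Cobienia,0,AV,yes,0.77,True
Cobienia,200,MV,yes,0.70,True
Cobienia,200,AV,yes,0.62,True
Cobienia,1000,MV,yes,0.77,True
Cobienia,1000,AV,yes,0.76,True
Cobienia,2500,MV,yes,0.79,True
Cobienia,2500,AV,yes,0.79,True
Cobienia,4000,MV,yes,0.73,True
Cobienia,4000,AV,yes,0.84,True
Gastatus,0,MV,yes,0.84,True
Gastatus,0,AV,yes,0.78,True
Gastatus,200,MV,yes,0.70,True
Gastatus,200,AV,yes,0.81,True
Gastatus,1000,MV,yes,0.61,True
Gastatus,1000,AV,yes,0.84,True
Gastatus,2500,MV,yes,0.68,True
Gastatus,2500,AV,yes,0.92,True
Gastatus,4000,MV,yes,0.71,True
Gastatus,4000,AV,yes,0.83,True
Gobiobio,0,MV,yes,0.91,True
Gobiobio,0,AV,yes,0.73,True
Gobiobio,200,MV,yes,0.92,True
Gobiobio,200,AV,yes,0.85,True
Gobiobio,1000,MV,yes,0.92,True
Gobiobio,1000,AV,yes,0.88,True
Gobiobio,2500,MV,yes,0.97,True
Gobiobio,2500,AV,yes,0.84,True
Gobiobio,4000,MV,yes,0.89,True
Gobiobio,4000,AV,yes,0.86,True
Gymnrnua,0,MV,yes,0.69,True
Gymnrnua,0,AV,yes,0.77,True
Gymnrnua,200,MV,yes,0.77,True
Gymnrnua,200,AV,yes,0.79,True
Gymnrnua,1000,MV,yes,0.73,True
Gymnrnua,1000,AV,yes,0.68,True
Gymnrnua,2500,MV,yes,0.83,True
Gymnrnua,2500,AV,yes,0.75,True
Gymnrnua,4000,MV,yes,0.80,True
Gymnrnua,4000,AV,yes,0.75,True
Leucscus,0,MV,yes,0.79,True
Leucscus,0,AV,yes,0.78,True
Leucscus,200,MV,yes,0.73,True
Leucscus,200,AV,yes,0.79,True
Leucscus,1000,MV,yes,0.81,True
Leucscus,1000,AV,yes,0.74,True
Leucscus,2500,MV,yes,0.80,True
Leucscus,2500,AV,yes,0.68,True
Leucscus,4000,MV,yes,0.77,True
Leucscus,4000,AV,yes,0.79,True
Percilis,0,MV,yes,0.85,True
Percilis,0,AV,yes,0.85,True
Percilis,200,MV,yes,0.89,True
Percilis,200,AV,yes,0.83,True
Percilis,1000,MV,yes,0.80,True
Percilis,1000,AV,yes,0.87,True
Percilis,2500,MV,yes,0.78,True
Percilis,2500,AV,yes,0.89,True
Percilis,4000,MV,yes,0.86,True
Percilis,4000,AV,yes,0.83,True
Phoxinus,0,MV,yes,0.82,True
Phoxinus,0,AV,yes,0.92,True
Phoxinus,200,MV,yes,0.83,True
Phoxinus,200,AV,yes,0.87,True
Phoxinus,1000,MV,yes,0.83,True
Phoxinus,1000,AV,yes,0.83,True
Phoxinus,2500,MV,yes,0.88,True
Phoxinus,2500,AV,yes,0.90,True
Phoxinus,4000,MV,yes,0.94,True
Phoxinus,4000,AV,yes,0.88,True
Pungtius,0,MV,yes,0.68,True
Pungtius,0,AV,yes,0.64,True
Pungtius,200,MV,yes,0.58,True
Pungtius,200,AV,yes,0.73,True
Pungtius,1000,MV,yes,0.80,True
Pungtius,1000,AV,yes,0.76,True
Pungtius,2500,MV,yes,0.67,True
Pungtius,2500,AV,yes,0.71,True
Pungtius,4000,MV,yes,0.67,True
Pungtius,4000,AV,yes,0.74,True
Rutiilus,0,MV,yes,0.75,True
Rutiilus,0,AV,yes,0.77,True
Rutiilus,200,MV,yes,0.78,True
Rutiilus,200,AV,yes,0.76,True
Rutiilus,1000,MV,yes,0.72,True
Rutiilus,1000,AV,yes,0.74,True
Rutiilus,2500,MV,yes,0.81,True
Rutiilus,2500,AV,yes,0.80,True
Rutiilus,4000,MV,yes,0.78,True
Rutiilus,4000,AV,yes,0.81,True
Salmalar,0,MV,yes,0.97,True
Salmalar,0,AV,yes,0.93,True
Salmalar,200,MV,yes,0.98,True
Salmalar,200,AV,yes,0.93,True
Salmalar,1000,MV,yes,0.98,True
Salmalar,1000,AV,yes,0.92,True
Salmalar,2500,MV,yes,0.96,True
Salmalar,2500,AV,yes,0.95,True
Salmalar,4000,MV,yes,0.91,True
Salmalar,4000,AV,yes,0.92,True
Salmario,0,MV,yes,0.82,True
Salmario,0,AV,yes,0.77,True
Salmario,200,MV,yes,0.77,True
Salmario,200,AV,yes,0.74,True
Salmario,1000,MV,yes,0.80,True
Salmario,1000,AV,yes,0.86,True
Salmario,2500,MV,yes,0.80,True
Salmario,2500,AV,yes,0.69,True
Salmario,4000,MV,yes,0.76,True
Salmario,4000,AV,yes,0.62,True
Tincinca,0,MV,yes,0.58,True
Tincinca,0,AV,yes,0.63,True
Tincinca,200,MV,yes,0.67,True
Tincinca,200,AV,yes,0.65,True
Tincinca,1000,MV,yes,0.49,True
Tincinca,1000,AV,yes,0.78,True
Tincinca,2500,MV,yes,0.62,True
Tincinca,2500,AV,yes,0.72,True
Tincinca,4000,MV,yes,0.75,True
Tincinca,4000,AV,yes,0.72,True
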